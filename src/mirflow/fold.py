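"""RNA secondary-structure folding backends.

The default backend is the ViennaRNA nearest-neighbour minimum-free-energy
(MFE) folder via its Python bindings.  A simplified stacking-energy dynamic
program (``simple`` backend) is bundled so that structure-dependent logic can
be exercised without the thermodynamic parameter tables; hairpin-criteria
tests are designed with >= 5 kcal/mol margin so the backend choice cannot
flip a verdict.

Energies are in kcal/mol; structures are dot-bracket strings over "()." of
the same length as the sequence.
"""

from __future__ import annotations

import functools
import math

from ._util import to_rna, validate_alphabet

MAX_FOLD_LENGTH = 1000

#: simplified model constants
_STACK_E = -2.0  # per stacked pair
_HAIRPIN_E = 3.0  # closing a hairpin loop
_INTERNAL_E = 1.0  # bulge / interior loop
_MULTI_E = 2.0  # multibranch closure
_MIN_HAIRPIN = 3  # unpaired bases enclosed by a pair

_CAN_PAIR = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}


def fold_rna(seq: str, backend: str = "vienna") -> tuple[str, float]:
    """Fold a sequence, returning ``(dot_bracket, mfe_kcal_mol)``.

    Deterministic for a fixed backend and sequence.  DNA input is treated
    as RNA (T read as U).
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if len(seq) > MAX_FOLD_LENGTH:
        raise ValueError(f"sequence longer than {MAX_FOLD_LENGTH} nt")
    validate_alphabet(seq)
    rna = to_rna(seq)
    if backend == "vienna":
        return _fold_vienna(rna)
    if backend == "simple":
        return _fold_simple(rna)
    raise ValueError(f"unknown folding backend: {backend!r}")


def _fold_vienna(rna: str) -> tuple[str, float]:
    import RNA

    structure, mfe = RNA.fold(rna)
    return structure, float(mfe)


@functools.lru_cache(maxsize=4096)
def _fold_simple(rna: str) -> tuple[str, float]:
    """Zuker-style DP under the simplified energy model.

    O(n^3); intended for short sequences (unit tests, precursor-sized
    hairpins), not genome-scale scans.
    """
    n = len(rna)
    inf = math.inf

    def pairable(i: int, j: int) -> bool:
        return (rna[i], rna[j]) in _CAN_PAIR and j - i - 1 >= _MIN_HAIRPIN

    V = [[inf] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]

    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable(i, j):
                best = _HAIRPIN_E
                if pairable(i + 1, j - 1) and V[i + 1][j - 1] < inf:
                    best = min(best, V[i + 1][j - 1] + _STACK_E)
                # small bulges / interior loops only (<= 4 unpaired total)
                for p in range(i + 1, min(i + 4, j)):
                    for q in range(max(p + 1, j - 3), j):
                        if (p, q) == (i + 1, j - 1):
                            continue
                        if V[p][q] < inf:
                            best = min(best, V[p][q] + _INTERNAL_E)
                if j - i > 8:
                    best = min(best, W[i + 1][j - 1] + _MULTI_E)
                V[i][j] = best
            w = min(W[i + 1][j], W[i][j - 1])
            if V[i][j] < inf:
                w = min(w, V[i][j])
            for k in range(i + 1, j):
                cand = W[i][k - 1] + V[k][j] if V[k][j] < inf else inf
                if cand < w:
                    w = cand
            W[i][j] = min(w, 0.0)

    struct = ["."] * n

    def trace_V(i: int, j: int) -> None:
        struct[i], struct[j] = "(", ")"
        e = V[i][j]
        if pairable(i + 1, j - 1) and V[i + 1][j - 1] < inf and math.isclose(
            e, V[i + 1][j - 1] + _STACK_E
        ):
            trace_V(i + 1, j - 1)
            return
        for p in range(i + 1, min(i + 4, j)):
            for q in range(max(p + 1, j - 3), j):
                if (p, q) == (i + 1, j - 1):
                    continue
                if V[p][q] < inf and math.isclose(e, V[p][q] + _INTERNAL_E):
                    trace_V(p, q)
                    return
        if j - i > 8 and math.isclose(e, W[i + 1][j - 1] + _MULTI_E):
            trace_W(i + 1, j - 1)
        # else hairpin: nothing inside

    def trace_W(i: int, j: int) -> None:
        if i >= j or W[i][j] >= 0.0:
            return
        if math.isclose(W[i][j], W[i + 1][j]):
            trace_W(i + 1, j)
            return
        if math.isclose(W[i][j], W[i][j - 1]):
            trace_W(i, j - 1)
            return
        if V[i][j] < inf and math.isclose(W[i][j], V[i][j]):
            trace_V(i, j)
            return
        for k in range(i + 1, j):
            if V[k][j] < inf and math.isclose(W[i][j], W[i][k - 1] + V[k][j]):
                trace_W(i, k - 1)
                trace_V(k, j)
                return

    mfe = W[0][n - 1] if n > 1 else 0.0
    if mfe < 0.0:
        trace_W(0, n - 1)
    return "".join(struct), round(mfe, 2)


def pair_table(structure: str) -> list[int]:
    """Dot-bracket -> partner index per position (-1 for unpaired)."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"unexpected structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt
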