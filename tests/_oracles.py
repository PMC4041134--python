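"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the implementation it checks: exact rational arithmetic for the two-library
test, naive scanning for exact matching and target scoring, and a direct
structure-string walk for the hairpin criteria.
"""

from __future__ import annotations

from fractions import Fraction

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# exact two-library test, arbitrary precision


def ac_tails_exact(x: int, y: int, ratio: Fraction) -> tuple[Fraction, Fraction]:
    """Exact (C, D) via Fraction arithmetic.

    C sums the pmf directly; D uses the exact complement
    1 - sum_{k<=y-1} p(k|x), which is safe in rational arithmetic.
    """
    r = Fraction(ratio)
    p = Fraction(1, 1) / (1 + r) ** (x + 1)  # p(0|x)
    csum = p
    prev = Fraction(0)
    for k in range(y):
        if k == y - 1:
            prev = csum
        p = p * r * (x + k + 1) / ((k + 1) * (1 + r))
        csum += p
    if y == 0:
        prev = Fraction(0)
    return csum, 1 - prev


def ac_tail_rows_exact(
    x: int, y_max: int, ratio: Fraction
) -> tuple[list[Fraction], list[Fraction]]:
    """Exact C and D for all y in 0..y_max at fixed x (incremental)."""
    r = Fraction(ratio)
    p = Fraction(1, 1) / (1 + r) ** (x + 1)
    cs: list[Fraction] = [p]
    for k in range(y_max):
        p = p * r * (x + k + 1) / ((k + 1) * (1 + r))
        cs.append(cs[-1] + p)
    ds = [Fraction(1)] + [1 - cs[k] for k in range(y_max)]
    return cs, ds


def ac_pvalue_exact(x: int, y: int, ratio: Fraction) -> Fraction:
    c, d = ac_tails_exact(x, y, ratio)
    return min(Fraction(1), 2 * min(c, d))


# ---------------------------------------------------------------------------
# exact substring matching


def naive_hits(genome: dict[str, str], query: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of query on both strands, O(n*m) scan."""
    hits = []
    probes = {"+": query, "-": revcomp(query)}
    for chrom, seq in genome.items():
        for strand, probe in probes.items():
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                hits.append((chrom, i, strand))
                start = i + 1
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# target-penalty scoring, plain per-window loop

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}


def score_window_naive(mirna: str, window: str) -> tuple[float, set[str]]:
    """Penalty and flags for one gapless window, straightforward loop."""
    L = len(mirna)
    assert len(window) == L
    penalty = 0.0
    seed_mm = 0
    flags: set[str] = set()
    for i in range(L):
        mb, tb = mirna[i], window[L - 1 - i]
        pos = i + 1
        weight = 2.0 if 2 <= pos <= 13 else 1.0
        if (mb, tb) in _WC:
            continue
        if (mb, tb) in _WOBBLE:
            penalty += 0.5 * weight
        else:
            penalty += 1.0 * weight
            if 2 <= pos <= 12:
                seed_mm += 1
            if pos in (10, 11):
                flags.add("cleavage_site_mismatch")
    if seed_mm > 1:
        flags.add("seed_mismatches")
    return penalty, flags


def scan_naive(mirna: str, transcript: str, max_penalty: float):
    """All windows at or below max_penalty: (start, penalty, flags)."""
    L = len(mirna)
    out = []
    for o in range(len(transcript) - L + 1):
        pen, flags = score_window_naive(mirna, transcript[o : o + L])
        if pen <= max_penalty + 1e-9:
            out.append((o, pen, flags))
    return out


# ---------------------------------------------------------------------------
# hairpin criteria, recomputed directly from the structure string


def _pairs_from_structure(structure: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    return pairs


def duplex_stats_naive(structure: str, m0: int, mlen: int):
    """Recompute duplex statistics per their definitions, independently.

    Returns a dict with the same fields as DuplexStats or None when the
    mature has no partner outside itself.
    """
    pairs = _pairs_from_structure(structure)
    m1 = m0 + mlen
    partnered = [
        (i, pairs[i])
        for i in range(m0, m1)
        if i in pairs and not (m0 <= pairs[i] < m1)
    ]
    if not partnered:
        return None
    partnered.sort(key=lambda t: t[1])
    groups = [[partnered[0]]]
    for t in partnered[1:]:
        if t[1] - groups[-1][-1][1] > 12:
            groups.append([])
        groups[-1].append(t)
    best = max(groups, key=len)
    mat_positions = sorted(i for i, _ in best)
    star_positions = sorted(j for _, j in best)
    star_lo, star_hi = star_positions[0], star_positions[-1]
    downstream = star_lo >= m1

    def longest_gap(span_lo, span_hi, member):
        best_run = run = 0
        for p in range(span_lo, span_hi + 1):
            if p in member:
                run = 0
            else:
                run += 1
                best_run = max(best_run, run)
        return best_run

    mat_set, star_set = set(mat_positions), set(star_positions)
    mb = longest_gap(mat_positions[0], mat_positions[-1], mat_set)
    sb = longest_gap(star_lo, star_hi, star_set)
    un_m = (mat_positions[-1] - mat_positions[0] + 1) - len(mat_set)
    un_s = (star_hi - star_lo + 1) - len(star_set)

    if downstream:
        hi_ext = min(star_hi + 2, len(structure) - 1)
        spacing = star_lo - m1
        gap_lo, gap_hi = mat_positions[-1], star_lo
    else:
        hi_ext = min(star_hi + 2, m0 - 1)
        spacing = m0 - (hi_ext + 1)
        gap_lo, gap_hi = star_hi, mat_positions[0]
    branches = 0
    for p in range(gap_lo + 1, gap_hi):
        q = pairs.get(p, -1)
        if q > p and q < gap_hi and all(
            r not in pairs for r in range(p + 1, q)
        ):
            branches += 1
    return {
        "star_start": star_lo,
        "star_end": hi_ext + 1,
        "paired_bases": len(best),
        "max_bulge": max(mb, sb),
        "asymmetry": abs(un_m - un_s),
        "spacing": spacing,
        "branches": branches,
    }


def hairpin_verdict_naive(candidate, params) -> set[str]:
    """Violated-criteria set, recomputed from the structure string."""
    stats = duplex_stats_naive(
        candidate.structure, candidate.mature_offset, candidate.mature_len
    )
    if stats is None:
        stats = {
            "paired_bases": 0,
            "max_bulge": 0,
            "asymmetry": 0,
            "spacing": 0,
        }
    bad = set()
    if not (params.min_mirna_len <= candidate.mature_len <= params.max_mirna_len):
        bad.add("mature_length")
    if candidate.mfe > params.max_free_energy:
        bad.add("free_energy")
    if stats["spacing"] > params.max_spacing:
        bad.add("spacing")
    if stats["paired_bases"] < params.min_duplex_pairs:
        bad.add("min_duplex_pairs")
    if stats["max_bulge"] > params.max_bulge:
        bad.add("max_bulge")
    if stats["asymmetry"] > params.max_asymmetry:
        bad.add("asymmetry")
    if candidate.genome_copies > params.max_genome_copies:
        bad.add("genome_copies")
    return bad
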