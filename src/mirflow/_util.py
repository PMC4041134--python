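"""Shared sequence helpers.

All sequences are stored internally in the DNA alphabet (T, not U); RNA
inputs are converted on read so that genome hits, miRBase-style catalogs
and sequenced tags compare exactly.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = frozenset("ACGTN")


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; alphabet preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_alphabet(seq: str, extra: str = "") -> None:
    allowed = DNA_ALPHABET | set(extra) | {"U"}
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")


def format_percent(count: int, total: int, places: int = 2) -> str:
    """Percentage string with half-up rounding, e.g. ``'23.09%'``.

    Round-half-up on the exact rational (not the float) so that printed
    summary tables are reproducible regardless of binary representation.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-places)
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP)
    return f"{pct}%"


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: DNA sequence} (order-preserving)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        out[rec.id] = to_dna(str(rec.seq))
    return out


def write_fasta(items, path) -> None:
    """Write an iterable of (id, seq) pairs as FASTA, 70-column wrapped."""
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
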