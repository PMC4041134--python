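"""Raw small-RNA read cleaning, tag collapsing and length distribution.

Raw Illumina sRNA reads carry the insert (the sequenced small RNA) followed
by the 3' sequencing adaptor.  Cleaning removes, in a fixed order, reads
that are low quality, 5'-adaptor contaminants, lack the 3' adaptor, contain
no insert, are poly-A artifacts, or whose insert is shorter than 18 nt.
Surviving inserts are collapsed to unique tags with occurrence counts; the
total number of clean reads is the normalisation denominator used by the
expression analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._util import to_dna

#: discard reasons, in the order they are evaluated
FILTER_REASONS = (
    "low_quality",
    "adaptor5_contaminant",
    "no_3prime_adaptor",
    "no_insert",
    "poly_A",
    "too_short",
)


@dataclass(frozen=True)
class ReadTag:
    """A unique insert sequence and its occurrence count in one library."""

    sequence: str
    count: int


@dataclass(frozen=True)
class CleaningConfig:
    """Cleaning rules.

    adaptor3 / adaptor5
        Adaptor sequences (DNA alphabet).  adaptor3 is required; detection
        uses an exact match of its first ``adaptor_seed`` bases, leftmost
        occurrence wins.  adaptor5 contamination is flagged when the read
        begins with the last ``adaptor_seed`` bases of adaptor5.
    min_len
        Minimum insert length kept (18 nt).
    max_len
        Inserts longer than this are kept as tags but flagged for exclusion
        from miRNA analysis downstream (default 30 nt).
    max_n_fraction / min_phred
        A read is low quality if >10% of its bases are N or any base is
        below Phred 10 (Sanger +33 encoding).
    polya_fraction / polya_run
        An insert is a poly-A artifact if >= 80% of its bases are A or it
        ends in a run of >= 10 A's.
    passthrough
        If True, a read with no 3' adaptor is taken whole as the insert
        (used for re-cleaning already-trimmed inserts; idempotence).
    """

    adaptor3: str
    adaptor5: str | None = None
    min_len: int = 18
    max_len: int = 30
    adaptor_seed: int = 8
    adaptor_mismatches: int = 0
    max_n_fraction: float = 0.10
    min_phred: int = 10
    polya_fraction: float = 0.80
    polya_run: int = 10
    passthrough: bool = False

    def __post_init__(self):
        if not self.adaptor3:
            raise ValueError("adaptor3 must be non-empty")
        object.__setattr__(self, "adaptor3", to_dna(self.adaptor3))
        if self.adaptor5 is not None:
            object.__setattr__(self, "adaptor5", to_dna(self.adaptor5))


@dataclass
class CleanReadSet:
    """Collapsed clean tags plus the cleaning audit trail."""

    tags: list[ReadTag]
    total_clean: int
    filter_stats: dict[str, int]
    n_raw: int

    def check(self) -> None:
        if self.total_clean + sum(self.filter_stats.values()) != self.n_raw:
            raise AssertionError("read-count conservation violated")
        if sum(t.count for t in self.tags) != self.total_clean:
            raise AssertionError("tag-count conservation violated")


def _find_adaptor(seq: str, adaptor: str, seed: int, mismatches: int) -> int:
    """Leftmost start of the adaptor seed in seq, or -1."""
    probe = adaptor[:seed]
    if mismatches == 0:
        return seq.find(probe)
    k = len(probe)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = sum(a != b for a, b in zip(window, probe))
        if mm <= mismatches:
            return i
    return -1


def _is_polya(insert: str, cfg: CleaningConfig) -> bool:
    if not insert:
        return False
    if insert.count("A") / len(insert) >= cfg.polya_fraction:
        return True
    run = len(insert) - len(insert.rstrip("A"))
    return run >= cfg.polya_run


def clean_read(
    sequence: str, quality: str | None, cfg: CleaningConfig
) -> tuple[str | None, str | None]:
    """Clean one read.

    Returns ``(insert, None)`` when all filters pass, else ``(None, reason)``
    with exactly one reason from :data:`FILTER_REASONS`, evaluated in that
    fixed order.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    seq = to_dna(sequence)

    if quality is not None and len(quality) == len(seq):
        if any(ord(q) - 33 < cfg.min_phred for q in quality):
            return None, "low_quality"
    if seq.count("N") / len(seq) > cfg.max_n_fraction:
        return None, "low_quality"

    if cfg.adaptor5:
        probe5 = cfg.adaptor5[-cfg.adaptor_seed :]
        if seq.startswith(probe5):
            return None, "adaptor5_contaminant"

    pos = _find_adaptor(seq, cfg.adaptor3, cfg.adaptor_seed, cfg.adaptor_mismatches)
    if pos < 0:
        if cfg.passthrough:
            insert = seq
        else:
            return None, "no_3prime_adaptor"
    elif pos == 0:
        return None, "no_insert"
    else:
        insert = seq[:pos]

    if _is_polya(insert, cfg):
        return None, "poly_A"
    if len(insert) < cfg.min_len:
        return None, "too_short"
    return insert, None


def iter_fastq(path):
    """Yield ``(identifier, sequence, quality)`` from a Sanger FASTQ file.

    Raises ``ValueError`` naming the record index on malformed records.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{idx}: {exc}") from exc
            yield rec
            idx += 1


def clean_reads(reads, cfg: CleaningConfig) -> CleanReadSet:
    """Clean an iterable of ``(id, sequence, quality)`` triples."""
    stats = {r: 0 for r in FILTER_REASONS}
    counts: Counter[str] = Counter()
    n_raw = 0
    for _ident, seq, qual in reads:
        n_raw += 1
        insert, reason = clean_read(seq, qual, cfg)
        if reason is not None:
            stats[reason] += 1
        else:
            counts[insert] += 1
    tags = [
        ReadTag(s, c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    out = CleanReadSet(
        tags=tags,
        total_clean=sum(counts.values()),
        filter_stats=stats,
        n_raw=n_raw,
    )
    out.check()
    return out


def clean_library(fastq_path, cfg: CleaningConfig) -> CleanReadSet:
    """Clean a FASTQ library and collapse to unique tags.

    Tags are ordered by descending count then lexicographic sequence, so
    output files are deterministic.
    """
    return clean_reads(iter_fastq(fastq_path), cfg)


def length_distribution(
    readset: CleanReadSet, lo: int = 18, hi: int = 30
) -> dict[object, int]:
    """Read counts per insert length over ``lo..hi``; others in ``'other'``.

    Counts are reads (tag counts), not unique tags, and sum to total_clean.
    """
    dist: dict[object, int] = {length: 0 for length in range(lo, hi + 1)}
    dist["other"] = 0
    for tag in readset.tags:
        n = len(tag.sequence)
        key = n if lo <= n <= hi else "other"
        dist[key] += tag.count
    return dist


def mirna_tags(readset: CleanReadSet, cfg: CleaningConfig) -> list[ReadTag]:
    """Tags within the length range analysed for miRNAs (min_len..max_len)."""
    return [t for t in readset.tags if cfg.min_len <= len(t.sequence) <= cfg.max_len]


def write_tags_fasta(readset: CleanReadSet, path) -> None:
    """Collapsed tags in ``>tag<rank>_x<count>`` dialect."""
    with open(path, "w") as fh:
        for rank, tag in enumerate(readset.tags, start=1):
            fh.write(f">tag{rank}_x{tag.count}\n{tag.sequence}\n")


def write_filter_stats(readset: CleanReadSet, path) -> None:
    import pandas as pd

    rows = [("clean", readset.total_clean)] + [
        (k, v) for k, v in readset.filter_stats.items()
    ]
    pd.DataFrame(rows, columns=["class", "reads"]).to_csv(path, sep="\t", index=False)


def rebuild_from_tags(tags: list[ReadTag]) -> CleanReadSet:
    """Wrap already-clean tags as a CleanReadSet (internal re-runs)."""
    total = sum(t.count for t in tags)
    return CleanReadSet(
        tags=sorted(tags, key=lambda t: (-t.count, t.sequence)),
        total_clean=total,
        filter_stats={r: 0 for r in FILTER_REASONS},
        n_raw=total,
    )
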