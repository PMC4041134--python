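"""Perfect-match genome mapping and the sRNA annotation cascade.

Clean tags are mapped to the genome requiring exact full-length matches on
either strand (no mismatches, no gaps — only perfectly mapped sequences are
retained).  Each tag is then assigned a single annotation category by a
priority cascade: a perfect match to a mature miRNA catalog beats ncRNA
annotation (rRNA > tRNA > snRNA > snoRNA), which beats gene-structure
categories (exon/intron, sense/antisense), and anything left is
unannotated — the search space for novel miRNA prediction.  The per-library
tally mirrors the standard unique/total summary table with percentages of
library-wide unique tags and total clean reads.

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
inclusive.  Sequences are stored as DNA; RNA input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from ._util import format_percent, read_fasta, revcomp, to_dna
from .preprocess import ReadTag

DEFAULT_PRIORITY = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
)

CATEGORIES = DEFAULT_PRIORITY + ("unannotated",)

#: ncRNA feature types classified sense-strand-only by default
_NCRNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA")


class GenomeIndex:
    """Exact-match lookup over both strands of a genome.

    Seeds a dictionary of all k-mers (default k=18, the minimum tag
    length) on the forward strand and verifies full-length extensions, so
    ``lookup(s)`` returns every position where ``s`` occurs exactly,
    forward or as reverse complement, and nothing else.  Positions are
    forward-strand 0-based starts of the occupied interval.
    """

    def __init__(self, genome: dict[str, str], k: int = 18):
        seen = set()
        for name in genome:
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name}")
            seen.add(name)
        self.genome = {name: to_dna(seq) for name, seq in genome.items()}
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((chrom, i))

    @classmethod
    def from_fasta(cls, path, k: int = 18) -> "GenomeIndex":
        return cls(read_fasta(path), k=k)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def _lookup_forward(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, i in self._seeds.get(query[: self.k], ()):
            if self.genome[chrom][i : i + len(query)] == query:
                hits.append((chrom, i))
        return hits

    def lookup(self, seq: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``seq`` as ``(chrom, start, strand)``."""
        query = to_dna(seq)
        if len(query) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        hits = [(c, p, "+") for c, p in self._lookup_forward(query)]
        rc = revcomp(query)
        if rc != query:
            hits += [(c, p, "-") for c, p in self._lookup_forward(rc)]
        else:  # palindromic query: one genomic interval, both strands
            hits += [(c, p, "-") for c, p in self._lookup_forward(rc)]
        return sorted(set(hits))


@dataclass
class AnnotationTracks:
    """Strand-aware interval lookup of genome features by type.

    Introns are derived: a position is intronic for a gene/transcript if it
    lies within the feature span but overlaps none of its exons.
    """

    exons: dict[str, IntervalTree] = field(default_factory=dict)
    genes: dict[str, IntervalTree] = field(default_factory=dict)
    ncrna: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_gff3(cls, path) -> "AnnotationTracks":
        import gffutils

        tracks = cls()
        try:
            db = gffutils.create_db(
                str(path),
                ":memory:",
                merge_strategy="create_unique",
                keep_order=True,
            )
            for feat in db.all_features():
                if feat.start is None or feat.end is None:
                    raise ValueError(
                        f"malformed GFF3 {path}: feature without coordinates"
                    )
                # GFF3 1-based inclusive -> 0-based half-open
                tracks.add_feature(
                    feat.featuretype, feat.seqid, feat.start - 1, feat.end, feat.strand
                )
        except ValueError:
            raise
        except Exception as exc:
            raise ValueError(f"malformed GFF3 {path}: {exc}") from exc
        return tracks

    def add_feature(
        self, ftype: str, chrom: str, start: int, end: int, strand: str
    ) -> None:
        if end <= start:
            raise ValueError(f"empty feature {ftype} {chrom}:{start}-{end}")
        if ftype in _NCRNA_TYPES:
            self.ncrna.setdefault((ftype, chrom), IntervalTree()).addi(
                start, end, strand
            )
        elif ftype == "exon":
            self.exons.setdefault(chrom, IntervalTree()).addi(start, end, strand)
        elif ftype in ("gene", "mRNA", "transcript"):
            self.genes.setdefault(chrom, IntervalTree()).addi(start, end, strand)
        # other types (miRNA_primary_transcript etc.) are not cascade tracks

    def _overlaps(
        self, tree: IntervalTree | None, start: int, end: int, strand: str | None
    ) -> bool:
        if tree is None:
            return False
        for iv in tree.overlap(start, end):
            if strand is None or iv.data == strand:
                return True
        return False

    def hit_category(
        self, chrom: str, start: int, end: int, strand: str
    ) -> set[str]:
        """All cascade categories a genomic hit is eligible for."""
        cats: set[str] = set()
        for ftype in _NCRNA_TYPES:
            if self._overlaps(self.ncrna.get((ftype, chrom)), start, end, strand):
                cats.add(ftype)
        exon_tree = self.exons.get(chrom)
        gene_tree = self.genes.get(chrom)
        for feat_strand in ("+", "-"):
            sense = "sense" if feat_strand == strand else "antisense"
            in_exon = False
            if exon_tree is not None:
                for iv in exon_tree.overlap(start, end):
                    if iv.data == feat_strand:
                        in_exon = True
                        break
            if in_exon:
                cats.add(f"exon_{sense}")
            elif gene_tree is not None:
                for iv in gene_tree.overlap(start, end):
                    if iv.data == feat_strand:
                        cats.add(f"intron_{sense}")
                        break
        return cats


class MatureCatalog:
    """Known mature miRNA catalog (miRBase-style FASTA)."""

    def __init__(self, entries: list[tuple[str, str]]):
        if not entries:
            raise ValueError("empty mature miRNA database")
        self.entries = [(name, to_dna(seq)) for name, seq in entries]
        self._by_seq: dict[str, list[str]] = {}
        for name, seq in self.entries:
            self._by_seq.setdefault(seq, []).append(name)

    @classmethod
    def from_fasta(cls, path) -> "MatureCatalog":
        fasta = read_fasta(path)
        return cls(list(fasta.items()))

    def match(self, tag_sequence: str) -> tuple[str | None, list[str]]:
        """Perfect-match identification of a conserved miRNA.

        Returns ``(identifier, all_matching_identifiers)``; the identifier
        is the first in file order (tie rule), None when no catalog entry
        equals the tag exactly.  IsomiRs (±1 terminal base, internal
        mismatches) do not match.
        """
        matches = self._by_seq.get(to_dna(tag_sequence), [])
        return (matches[0] if matches else None), list(matches)


def match_known_mirna(tag: ReadTag | str, catalog: MatureCatalog) -> str | None:
    seq = tag.sequence if isinstance(tag, ReadTag) else tag
    return catalog.match(seq)[0]


@dataclass
class TagAnnotation:
    sequence: str
    count: int
    category: str
    mapped: bool
    hits: list[tuple[str, int, str]]
    mirna_id: str | None = None
    mirna_ids_all: list[str] = field(default_factory=list)


def classify_read(
    tag: ReadTag,
    index: GenomeIndex,
    tracks: AnnotationTracks,
    catalog: MatureCatalog | None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> TagAnnotation:
    """Assign exactly one category to a tag by the priority cascade.

    Genome-unmapped tags are eligible only for miRNA (catalog match) or
    unannotated.
    """
    hits = index.lookup(tag.sequence)
    mirna_id, all_ids = (None, [])
    if catalog is not None:
        mirna_id, all_ids = catalog.match(tag.sequence)

    eligible: set[str] = set()
    if mirna_id is not None:
        eligible.add("miRNA")
    for chrom, start, strand in hits:
        end = start + len(tag.sequence)
        eligible |= tracks.hit_category(chrom, start, end, strand)

    category = "unannotated"
    for cat in priority:
        if cat in eligible:
            category = cat
            break
    return TagAnnotation(
        sequence=tag.sequence,
        count=tag.count,
        category=category,
        mapped=bool(hits),
        hits=hits,
        mirna_id=mirna_id,
        mirna_ids_all=all_ids,
    )


def annotate_library(
    tags: list[ReadTag],
    index: GenomeIndex,
    tracks: AnnotationTracks,
    catalog: MatureCatalog | None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> list[TagAnnotation]:
    return [classify_read(t, index, tracks, catalog, priority) for t in tags]


def tally_categories(
    annotations: list[TagAnnotation],
    unique_total: int | None = None,
    read_total: int | None = None,
) -> pd.DataFrame:
    """Unique/total counts and percentages per category (summary table).

    Percentages use library-wide unique tag and total clean read
    denominators and are formatted half-up to two decimals, so printed
    count/total pairs reproduce exactly.
    """
    if unique_total is None:
        unique_total = len(annotations)
    if read_total is None:
        read_total = sum(a.count for a in annotations)
    if unique_total <= 0 or read_total <= 0:
        raise ValueError("library totals must be positive")

    rows = []
    mapped_u = sum(1 for a in annotations if a.mapped)
    mapped_t = sum(a.count for a in annotations if a.mapped)
    rows.append(("mapped_to_genome", mapped_u, mapped_t))
    for cat in CATEGORIES:
        sub = [a for a in annotations if a.category == cat]
        rows.append((cat, len(sub), sum(a.count for a in sub)))

    df = pd.DataFrame(rows, columns=["category", "unique", "total"])
    df["unique_pct"] = [format_percent(u, unique_total) for u in df["unique"]]
    df["total_pct"] = [format_percent(t, read_total) for t in df["total"]]
    return df


def known_mirna_counts(annotations: list[TagAnnotation]) -> dict[str, int]:
    """Per-identifier read counts over tags perfectly matching the catalog."""
    counts: dict[str, int] = {}
    for a in annotations:
        if a.category == "miRNA" and a.mirna_id is not None:
            counts[a.mirna_id] = counts.get(a.mirna_id, 0) + a.count
    return counts


def write_classifications(annotations: list[TagAnnotation], path) -> None:
    rows = [
        (
            a.sequence,
            a.count,
            a.category,
            int(a.mapped),
            a.mirna_id or "",
            ";".join(f"{c}:{p}:{s}" for c, p, s in a.hits),
        )
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["sequence", "count", "category", "mapped", "mirna_id", "hits"]
    ).to_csv(path, sep="\t", index=False)
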