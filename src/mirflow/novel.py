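"""Novel miRNA prediction from unannotated genome-mapped tags.

A candidate locus is anchored on an unannotated tag with a perfect genome
hit.  The locus is extended to allow a miRNA* (star) partner within the
maximal miRNA/miRNA* spacing, folded, and the mature/star duplex is read
off the predicted secondary structure assuming the canonical Dicer 2-nt 3'
overhang.  A candidate is accepted when it satisfies all of the hairpin
criteria: mature length within bounds, precursor minimum free energy at or
below the threshold (default -18 kcal/mol), mature-star spacing at most
300 nt, at least 16 mature bases paired to the star, largest interior bulge
at most 4 nt, duplex asymmetry at most 4 nt, and at most 20 perfect genome
copies of the mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import revcomp, to_dna
from .annotate import GenomeIndex
from .fold import fold_rna, pair_table

__all__ = [
    "NovelPredictionParams",
    "DuplexStats",
    "HairpinCandidate",
    "Verdict",
    "NovelMiRNA",
    "fold",
    "derive_duplex",
    "evaluate_candidate",
    "extract_candidate_loci",
    "predict_novel",
]

#: criteria names reported by evaluate_candidate
CRITERIA = (
    "mature_length",
    "free_energy",
    "spacing",
    "min_duplex_pairs",
    "max_bulge",
    "asymmetry",
    "genome_copies",
)


@dataclass(frozen=True)
class NovelPredictionParams:
    """Hairpin-prediction thresholds (Mireap-style).

    Lengths in nt, energy in kcal/mol.  ``min_star_len``/``max_star_len``
    bound the reported star sequence length and size the candidate search
    window; they are not a pass/fail criterion by default.
    """

    min_mirna_len: int = 18
    max_mirna_len: int = 25
    min_star_len: int = 20
    max_star_len: int = 23
    max_genome_copies: int = 20
    max_free_energy: float = -18.0
    max_spacing: int = 300
    min_duplex_pairs: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank: int = 20

    def __post_init__(self):
        if self.min_mirna_len > self.max_mirna_len:
            raise ValueError("min_mirna_len > max_mirna_len")
        if self.min_star_len > self.max_star_len:
            raise ValueError("min_star_len > max_star_len")
        if self.max_free_energy >= 0:
            raise ValueError("max_free_energy must be negative")


@dataclass(frozen=True)
class DuplexStats:
    """Geometry of the mature/miRNA* duplex read from a structure."""

    star_start: int  # precursor coordinates, half-open, incl. 2-nt overhang
    star_end: int
    paired_bases: int
    max_bulge: int
    asymmetry: int
    spacing: int  # nt strictly between mature and star regions
    #: terminal loops strictly between the arms; 0 for a blunt loop, 1 when
    #: the stem continues inward, >= 2 means the precursor bifurcates
    branches: int = 0

    @property
    def star_length(self) -> int:
        return self.star_end - self.star_start


_NO_DUPLEX = DuplexStats(0, 0, 0, 0, 0, 0)

#: partners further apart than this belong to different helices; interior
#: loops inside a genuine miRNA/miRNA* duplex are far smaller (bulge <= 4)
_STAR_CLUSTER_GAP = 12


@dataclass
class HairpinCandidate:
    """A folded candidate precursor with its mature arm placement."""

    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    precursor: str  # precursor-oriented (5'->3'), DNA alphabet
    structure: str
    mfe: float
    mature_offset: int  # within precursor
    mature_len: int
    genome_copies: int = 1
    duplex: DuplexStats = _NO_DUPLEX
    support: dict[str, int] = field(default_factory=dict)

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_offset : self.mature_offset + self.mature_len]


@dataclass(frozen=True)
class Verdict:
    passed: bool
    reasons: tuple[str, ...] = ()


def fold(sequence: str, backend: str = "vienna") -> tuple[str, float]:
    """MFE fold; see :func:`mirflow.fold.fold_rna`."""
    return fold_rna(sequence, backend=backend)


def _runs_of_unpaired(flags: list[bool]) -> int:
    """Longest True-run (unpaired) strictly interior to the flag list."""
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def derive_duplex(
    structure: str, mature_offset: int, mature_len: int
) -> DuplexStats:
    """Locate the star arm and measure duplex statistics.

    The star is the region base-paired to the mature arm, extended by the
    conventional 2-nt 3' overhang (always at the star's higher-index end,
    which pairs opposite the mature 5' end in a nested hairpin).  Interior
    bulges and asymmetry are measured within the pairing span on each
    strand, excluding the overhang.  A mature arm with no pairing partner
    outside itself yields zero statistics rather than an error.
    """
    n = len(structure)
    m0, m1 = mature_offset, mature_offset + mature_len
    if not (0 <= m0 < m1 <= n):
        raise ValueError("mature arm outside precursor")
    pt = pair_table(structure)

    candidates = []  # (mature pos, partner), partner outside the mature
    for i in range(m0, m1):
        j = pt[i]
        if j < 0 or m0 <= j < m1:  # unpaired or self-pairing within mature
            continue
        candidates.append((i, j))
    if not candidates:
        return _NO_DUPLEX
    # the star is one helix, not the envelope of every partner: cluster
    # partners by proximity and keep the cluster pairing the most mature
    # bases (stray long-range pairs otherwise inflate the bulge).  Clusters
    # cannot straddle the mature arm, which separates the two sides by more
    # than the cluster gap.
    candidates.sort(key=lambda ij: ij[1])
    clusters: list[list[tuple[int, int]]] = [[candidates[0]]]
    for ij in candidates[1:]:
        if ij[1] - clusters[-1][-1][1] > _STAR_CLUSTER_GAP:
            clusters.append([])
        clusters[-1].append(ij)
    pairs = max(clusters, key=len)

    partners = [j for _, j in pairs]
    star_lo, star_hi = min(partners), max(partners)
    star_is_downstream = star_lo >= m1

    # mature-side span between outermost paired mature positions
    mat_paired = sorted(i for i, _ in pairs)
    mat_span = range(mat_paired[0], mat_paired[-1] + 1)
    paired_set = {i for i, _ in pairs}
    mat_flags = [i not in paired_set for i in mat_span]
    partner_set = set(partners)
    star_flags = [j not in partner_set for j in range(star_lo, star_hi + 1)]

    max_bulge = max(_runs_of_unpaired(mat_flags), _runs_of_unpaired(star_flags))
    asymmetry = abs(sum(mat_flags) - sum(star_flags))

    # 2-nt 3' overhang extends the star past its pairing span at the
    # higher-index end; clip to the precursor and to the mature arm.
    star_hi_ext = star_hi + 2
    if star_is_downstream:
        star_hi_ext = min(star_hi_ext, n - 1)
        spacing = star_lo - m1
        inter = (mat_paired[-1], star_lo)
    else:
        star_hi_ext = min(star_hi_ext, m0 - 1)
        spacing = m0 - (star_hi_ext + 1)
        inter = (star_hi, mat_paired[0])

    # terminal loops strictly between the arms (stem-loop vs bifurcation)
    branches = 0
    lo, hi = inter
    for p in range(lo + 1, hi):
        q = pt[p]
        if q > p and q < hi and all(pt[r] < 0 for r in range(p + 1, q)):
            branches += 1

    return DuplexStats(
        star_start=star_lo,
        star_end=star_hi_ext + 1,
        paired_bases=len(pairs),
        max_bulge=max_bulge,
        asymmetry=asymmetry,
        spacing=spacing,
        branches=branches,
    )


def evaluate_candidate(
    candidate: HairpinCandidate, params: NovelPredictionParams
) -> Verdict:
    """Apply all hairpin criteria; FAIL lists every violated criterion."""
    d = candidate.duplex
    reasons = []
    if not (params.min_mirna_len <= candidate.mature_len <= params.max_mirna_len):
        reasons.append("mature_length")
    if candidate.mfe > params.max_free_energy:
        reasons.append("free_energy")
    if d.spacing > params.max_spacing:
        reasons.append("spacing")
    if d.paired_bases < params.min_duplex_pairs:
        reasons.append("min_duplex_pairs")
    if d.max_bulge > params.max_bulge:
        reasons.append("max_bulge")
    if d.asymmetry > params.max_asymmetry:
        reasons.append("asymmetry")
    if candidate.genome_copies > params.max_genome_copies:
        reasons.append("genome_copies")
    return Verdict(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class CandidateLocus:
    """A genomic window to fold, with the anchor tag's placement inside."""

    chrom: str
    start: int
    end: int
    strand: str
    anchor_start: int  # genomic
    anchor_len: int
    star_downstream_in_precursor: bool


def _windows_for_hit(
    chrom: str,
    hit_start: int,
    tag_len: int,
    chrom_len: int,
    strand: str,
    params: NovelPredictionParams,
) -> list[CandidateLocus]:
    """Two candidate windows per hit: star 3' of the mature, or star 5'.

    Window arms are sized flank + max_spacing + max_star_len; coordinates
    are clipped to the chromosome, never an error.
    """
    reach = params.flank + params.max_spacing + params.max_star_len
    hit_end = hit_start + tag_len
    genomic_down = (
        max(0, hit_start - params.flank),
        min(chrom_len, hit_end + reach),
    )
    genomic_up = (
        max(0, hit_start - reach),
        min(chrom_len, hit_end + params.flank),
    )
    loci = []
    for (w0, w1), star_after_in_genome in ((genomic_down, True), (genomic_up, False)):
        # on the minus strand the precursor is the reverse complement, so
        # "downstream in the precursor" flips genomic direction
        star_downstream = star_after_in_genome if strand == "+" else not star_after_in_genome
        loci.append(
            CandidateLocus(
                chrom=chrom,
                start=w0,
                end=w1,
                strand=strand,
                anchor_start=hit_start,
                anchor_len=tag_len,
                star_downstream_in_precursor=star_downstream,
            )
        )
    # try the window whose star side is downstream of the mature in the
    # precursor first (mature on the 5' arm, the commoner configuration)
    loci.sort(key=lambda l: not l.star_downstream_in_precursor)
    return loci


def extract_candidate_loci(
    tag_hits: list[tuple[str, list[tuple[str, int, str]]]],
    chrom_lengths: dict[str, int],
    params: NovelPredictionParams,
) -> list[CandidateLocus]:
    """Candidate windows for every (tag, hit); multi-copy tags excluded.

    ``tag_hits`` is a list of (tag sequence, perfect hits); tags with more
    than ``max_genome_copies`` hits are dropped entirely.
    """
    out = []
    for seq, hits in tag_hits:
        if not hits or len(hits) > params.max_genome_copies:
            continue
        for chrom, pos, strand in hits:
            out.extend(
                _windows_for_hit(
                    chrom, pos, len(seq), chrom_lengths[chrom], strand, params
                )
            )
    return out


def build_candidate(
    locus: CandidateLocus,
    genome: dict[str, str],
    genome_copies: int,
    backend: str = "vienna",
    trim_flank: int | None = None,
) -> HairpinCandidate:
    """Extract, orient, fold and measure one candidate window.

    With ``trim_flank`` set, the precursor is excised after the window
    fold: the region from mature to star extended by the flank is cut
    out, refolded in isolation, and the duplex re-derived.  A genuine
    hairpin is locally stable and survives excision; chance window-level
    structure usually does not.  The returned candidate then carries the
    excised precursor and its coordinates.
    """
    seq = genome[locus.chrom][locus.start : locus.end]
    if locus.strand == "+":
        precursor = to_dna(seq)
        mature_offset = locus.anchor_start - locus.start
    else:
        precursor = to_dna(revcomp(seq))
        mature_offset = locus.end - (locus.anchor_start + locus.anchor_len)
    structure, mfe = fold_rna(precursor, backend=backend)
    duplex = derive_duplex(structure, mature_offset, locus.anchor_len)
    start, end = locus.start, locus.end

    if trim_flank is not None and duplex.paired_bases > 0:
        m0, m1 = mature_offset, mature_offset + locus.anchor_len
        t0 = max(0, min(m0, duplex.star_start) - trim_flank)
        t1 = min(len(precursor), max(m1, duplex.star_end) + trim_flank)
        precursor = precursor[t0:t1]
        mature_offset -= t0
        structure, mfe = fold_rna(precursor, backend=backend)
        duplex = derive_duplex(structure, mature_offset, locus.anchor_len)
        if locus.strand == "+":
            start, end = locus.start + t0, locus.start + t1
        else:  # precursor position p maps to genomic coordinate end-1-p
            start, end = locus.end - t1, locus.end - t0

    cand = HairpinCandidate(
        chrom=locus.chrom,
        start=start,
        end=end,
        strand=locus.strand,
        precursor=precursor,
        structure=structure,
        mfe=mfe,
        mature_offset=mature_offset,
        mature_len=locus.anchor_len,
        genome_copies=genome_copies,
    )
    cand.duplex = duplex
    return cand


@dataclass
class NovelMiRNA:
    """An accepted novel miRNA with per-library read support."""

    mirna_id: str
    mature: str
    candidate: HairpinCandidate
    counts: dict[str, int]

    @property
    def locus(self) -> tuple[str, int, int, str]:
        c = self.candidate
        return (c.chrom, c.start, c.end, c.strand)


def predict_novel(
    tag_counts: dict[str, dict[str, int]],
    index: GenomeIndex,
    params: NovelPredictionParams = NovelPredictionParams(),
    min_support: int = 5,
    backend: str = "vienna",
    max_branches: int = 1,
) -> list[NovelMiRNA]:
    """Predict novel miRNAs from unannotated tags.

    Besides the threshold criteria, an accepted precursor must be an
    unbranched stem-loop: at most ``max_branches`` terminal loop between
    the mature and star arms, per plant miRNA annotation practice.

    ``tag_counts`` maps tag sequence -> {library: count} for tags already
    classified unannotated in every library.  Tags are processed in
    descending total count, so the most abundant tag at a locus defines
    the mature arm (Dicer-cleavage proxy); less abundant tags whose hits
    fall on an accepted mature arm (within 2 nt) contribute their counts,
    and hits inside an accepted precursor are otherwise skipped
    (deduplication by precursor locus).  Output is locus-sorted.
    """
    chrom_lengths = index.chrom_lengths()
    order = sorted(
        (
            (seq, libs)
            for seq, libs in tag_counts.items()
            if params.min_mirna_len <= len(seq) <= params.max_mirna_len
            and sum(libs.values()) >= min_support
        ),
        key=lambda kv: (-sum(kv[1].values()), kv[0]),
    )

    accepted: list[NovelMiRNA] = []
    for seq, libs in order:
        hits = index.lookup(seq)
        if not hits or len(hits) > params.max_genome_copies:
            continue
        for chrom, pos, strand in hits:
            end = pos + len(seq)
            claimed = False
            for nov in accepted:
                c = nov.candidate
                if c.chrom != chrom:
                    continue
                if c.strand == strand:
                    arm0 = (
                        c.start + c.mature_offset
                        if c.strand == "+"
                        else c.end - c.mature_offset - c.mature_len
                    )
                    arm1 = arm0 + c.mature_len
                    if pos >= arm0 - 2 and end <= arm1 + 2:
                        for lib, cnt in libs.items():
                            nov.counts[lib] = nov.counts.get(lib, 0) + cnt
                        claimed = True
                        break
                # inside an accepted precursor (either strand): dedup —
                # the star arm of an accepted hairpin is not a new miRNA
                if pos < c.end and end > c.start:
                    claimed = True
                    break
            if claimed:
                continue
            for locus in _windows_for_hit(
                chrom, pos, len(seq), chrom_lengths[chrom], strand, params
            ):
                cand = build_candidate(
                    locus, index.genome, len(hits), backend, trim_flank=params.flank
                )
                if (
                    evaluate_candidate(cand, params).passed
                    and cand.duplex.branches <= max_branches
                ):
                    cand.support = dict(libs)
                    accepted.append(
                        NovelMiRNA(
                            mirna_id="",
                            mature=seq,
                            candidate=cand,
                            counts=dict(libs),
                        )
                    )
                    break

    accepted.sort(key=lambda nv: nv.locus)
    for i, nov in enumerate(accepted, start=1):
        nov.mirna_id = f"novel_mir_{i}"
    return accepted


def write_novel_outputs(novel: list[NovelMiRNA], outdir) -> None:
    """FASTA (mature + precursor), GFF3 loci and per-library count TSV."""
    import os

    import pandas as pd

    from ._util import write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta(
        [(f"{n.mirna_id}_mature", n.mature) for n in novel]
        + [(f"{n.mirna_id}_precursor", n.candidate.precursor) for n in novel],
        os.path.join(outdir, "novel_mirnas.fa"),
    )
    with open(os.path.join(outdir, "novel_loci.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for n in novel:
            c = n.candidate
            fh.write(
                f"{c.chrom}\tmirflow\tmiRNA_primary_transcript\t{c.start + 1}\t"
                f"{c.end}\t.\t{c.strand}\t.\tID={n.mirna_id}\n"
            )
    libs = sorted({lib for n in novel for lib in n.counts})
    rows = [
        [n.mirna_id, n.mature] + [n.counts.get(lib, 0) for lib in libs]
        for n in novel
    ]
    pd.DataFrame(rows, columns=["mirna_id", "mature"] + libs).to_csv(
        os.path.join(outdir, "novel_counts.tsv"), sep="\t", index=False
    )
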