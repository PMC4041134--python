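"""Synthetic two-condition small-RNA study generator.

Builds a toy genome carrying planted miRNA hairpin precursors (designed so
the hairpin evaluator passes every criterion with margin) and rRNA/tRNA-like
decoy loci, then simulates two sequencing libraries (control / treatment)
with known ground truth: planted expression levels, planted fold changes
for a subset of miRNAs, adaptor-carrying clean reads, and the junk read
classes the cleaning stage removes (poly-A, missing 3' adaptor, insertless,
sub-18-nt, low-quality).

Decoy loci are random sequences labelled with their category — synthetic
stand-ins for real ncRNA, sufficient to exercise the annotation cascade.
Each read's class is a single categorical draw, so every planted count is
Binomial(depth, p) — Poisson-like at these depths — and the number of FASTQ
records equals the library depth exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, to_dna
from .novel import (
    HairpinCandidate,
    NovelPredictionParams,
    derive_duplex,
    evaluate_candidate,
)
from .fold import fold_rna

#: design margins relative to the evaluator thresholds
DESIGN_PAIR_MARGIN = 2
DESIGN_BULGE_MARGIN = 2
DESIGN_ENERGY_MARGIN = 5.0  # kcal/mol

JUNK_CLASSES = ("poly_a", "no_adaptor", "no_insert", "too_short", "low_quality")


def _default_junk() -> dict[str, float]:
    return {
        "poly_a": 0.02,
        "no_adaptor": 0.05,
        "no_insert": 0.02,
        "too_short": 0.02,
        "low_quality": 0.01,
    }


def _default_length_weights() -> dict[int, float]:
    # 24-nt reads most abundant, then 22 and 21 nt, as in plant sRNA libraries
    return {20: 0.05, 21: 0.15, 22: 0.20, 23: 0.10, 24: 0.50}


def _default_fold_changes() -> list[float]:
    return [4.0, 4.0, 4.0, 4.0, 0.25, 0.25, 0.25, 0.25]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-library study.

    Defaults describe the standard conditions used throughout the test
    suite: 20 planted miRNAs (half in the known catalog), 4 up- and 4
    down-regulated at 4-fold (|log2fc| = 2), baseline abundances log-normal
    around ~400 TPM floored at 50 TPM, and 2x10^5 reads per library.
    """

    genome_length: int = 100_000
    n_mirnas: int = 20
    n_known: int = 10
    n_de_up: int = 4
    n_de_down: int = 4
    de_fold_changes: list[float] = field(default_factory=_default_fold_changes)
    baseline_log_tpm_mean: float = math.log(400.0)
    baseline_log_tpm_sigma: float = 0.8
    min_baseline_tpm: float = 50.0
    max_baseline_tpm: float = 20_000.0
    depth_control: int = 200_000
    depth_treatment: int = 200_000
    adaptor3: str = "TCGTATGCCGTCTTCTGCTTG"
    adaptor5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    read_length: int = 36
    junk_fractions: dict[str, float] = field(default_factory=_default_junk)
    n_decoys: int = 6
    decoy_min_fraction: float = 0.05
    background_fraction: float = 0.0
    n_background_positions: int = 60
    mature_length_weights: dict[int, float] = field(
        default_factory=_default_length_weights
    )
    dispersion: float | None = None  # negative-binomial overdispersion
    min_locus_gap: int = 100
    seed: int = 0

    def __post_init__(self):
        junk = sum(self.junk_fractions.values())
        if not all(0.0 <= f <= 1.0 for f in self.junk_fractions.values()):
            raise ValueError("junk fractions must lie in [0, 1]")
        if junk >= 1.0:
            raise ValueError("junk fractions must sum to < 1")
        if self.depth_control <= 0 or self.depth_treatment <= 0:
            raise ValueError("library depths must be positive")
        if any(fc <= 0 for fc in self.de_fold_changes):
            raise ValueError("fold changes must be positive")
        if self.n_de_up + self.n_de_down > self.n_mirnas:
            raise ValueError("more DE miRNAs than miRNAs")
        if len(self.de_fold_changes) != self.n_de_up + self.n_de_down:
            raise ValueError("de_fold_changes length must equal n_de_up + n_de_down")
        if self.n_known > self.n_mirnas:
            raise ValueError("n_known exceeds n_mirnas")


@dataclass
class MirnaTruth:
    mirna_id: str
    mature: str
    precursor: str
    chrom: str
    start: int  # genomic 0-based half-open, precursor locus
    end: int
    strand: str
    is_known: bool
    is_de: bool
    fold_change: float  # linear; 1.0 for non-DE
    baseline_tpm: float
    expected_count_control: float
    expected_count_treatment: float
    genome_copies: int = 1


@dataclass
class DecoyTruth:
    decoy_id: str
    category: str  # rRNA | tRNA
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str


@dataclass
class TruthTable:
    """Ground truth of one synthetic study."""

    spec: SyntheticSpec
    mirnas: list[MirnaTruth]
    decoys: list[DecoyTruth]
    background_pool: list[tuple[str, int, int, str]]  # chrom, start, end, strand

    def known_catalog(self) -> list[tuple[str, str]]:
        return [(m.mirna_id, m.mature) for m in self.mirnas if m.is_known]

    def novel_mirnas(self) -> list[MirnaTruth]:
        return [m for m in self.mirnas if not m.is_known]


_LOOP_BASES = "CAT"  # loop drawn from weakly pairing bases

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}


def _mutated_star(mature: str, rng: random.Random, n_mut: int) -> str:
    """Near-reverse-complement star: n_mut interior mismatches.

    Mismatch positions are kept >= 3 nt from the star ends and >= 4 nt
    apart, and the substituted base neither Watson-Crick- nor G:U-pairs
    the opposing mature base, so each mismatch is a clean 1-nt interior
    bulge on both strands.
    """
    star = list(revcomp(mature))
    L = len(star)
    positions: list[int] = []
    for _ in range(100):
        p = rng.randrange(3, L - 3)
        if all(abs(p - q) >= 4 for q in positions):
            positions.append(p)
            if len(positions) == n_mut:
                break
    for p in positions:
        m = mature[L - 1 - p]  # mature base opposing star position p
        banned = {_COMP[m], _WOBBLE_PARTNER.get(m, ""), star[p]}
        star[p] = rng.choice([b for b in "ACGT" if b not in banned])
    return "".join(star)


def design_precursor(
    mature: str,
    params: NovelPredictionParams = NovelPredictionParams(),
    seed: int = 0,
    backend: str = "vienna",
    max_attempts: int = 40,
) -> tuple[str, HairpinCandidate]:
    """Design a hairpin precursor that passes every criterion with margin.

    The mature sits on the 5' arm, followed by a short loop and a
    reverse-complement star arm.  The design is accepted only when the
    folded precursor passes the evaluator AND exceeds it with margin:
    >= min_duplex_pairs + 2 paired bases, bulge <= max_bulge - 2, and
    MFE <= max_free_energy - 5 kcal/mol.  Deterministic in (mature,
    params, seed).  Raises ``ValueError`` when no design is found (e.g. a
    homopolymer mature cannot form a sufficiently stable stem).
    """
    mature = to_dna(mature)
    if not (18 <= len(mature) <= 25):
        raise ValueError("mature length must be 18..25 nt")
    if set(mature) - set("ACGT"):
        raise ValueError("mature must contain only ACGU/ACGT")
    rng = random.Random(seed)
    # a near-reverse-complement star (interior mismatches) keeps the mature
    # sequence genomically unique: a perfect star would place an exact copy
    # of the mature on the opposite strand
    n_mut = 2 if len(mature) >= params.min_duplex_pairs + DESIGN_PAIR_MARGIN + 4 else 1
    for _ in range(max_attempts):
        star = _mutated_star(mature, rng, n_mut)
        loop = "".join(rng.choice(_LOOP_BASES) for _ in range(rng.randint(8, 12)))
        precursor = mature + loop + star
        structure, mfe = fold_rna(precursor, backend=backend)
        duplex = derive_duplex(structure, 0, len(mature))
        cand = HairpinCandidate(
            chrom="design",
            start=0,
            end=len(precursor),
            strand="+",
            precursor=precursor,
            structure=structure,
            mfe=mfe,
            mature_offset=0,
            mature_len=len(mature),
            genome_copies=1,
            duplex=duplex,
        )
        if (
            evaluate_candidate(cand, params).passed
            and duplex.paired_bases >= params.min_duplex_pairs + DESIGN_PAIR_MARGIN
            and duplex.max_bulge <= params.max_bulge - DESIGN_BULGE_MARGIN
            and mfe <= params.max_free_energy - DESIGN_ENERGY_MARGIN
        ):
            return precursor, cand
    raise ValueError(
        f"no satisfying precursor for mature {mature!r} after {max_attempts} attempts"
    )


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _draw_mature(rng: random.Random, spec: SyntheticSpec) -> str:
    lengths = sorted(spec.mature_length_weights)
    weights = [spec.mature_length_weights[k] for k in lengths]
    n = rng.choices(lengths, weights=weights)[0]
    # keep GC in a realistic band so the designed stem is comfortably stable
    while True:
        seq = _random_seq(rng, n)
        gc = (seq.count("G") + seq.count("C")) / n
        if 0.4 <= gc <= 0.7:
            return seq


def count_occurrences(genome: dict[str, str], query: str) -> int:
    """Exact occurrences of query on both strands (brute-force scan)."""
    total = 0
    rc = revcomp(query)
    for seq in genome.values():
        for probe in {query, rc}:
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def build_genome(
    spec: SyntheticSpec,
    params: NovelPredictionParams = NovelPredictionParams(),
    backend: str = "vienna",
) -> tuple[dict[str, str], TruthTable]:
    """Toy genome + ground truth.

    The genome is i.i.d. uniform ACGT background with each designed
    precursor spliced in exactly once (random strand) and decoy loci kept
    >= ``min_locus_gap`` apart from everything else.  Raises on placement
    collision after bounded retries.
    """
    rng = random.Random(spec.seed)
    chrom = "chr1"

    # --- design features -------------------------------------------------
    fold_changes = [1.0] * spec.n_mirnas
    de_flags = [False] * spec.n_mirnas
    de_idx = rng.sample(range(spec.n_mirnas), spec.n_de_up + spec.n_de_down)
    for j, idx in enumerate(de_idx):
        fold_changes[idx] = spec.de_fold_changes[j]
        de_flags[idx] = True
    known_idx = set(rng.sample(range(spec.n_mirnas), spec.n_known))

    matures: list[str] = []
    precursors: list[str] = []
    for i in range(spec.n_mirnas):
        for attempt in range(20):
            mature = _draw_mature(rng, spec)
            if mature in matures:
                continue
            try:
                prec, _ = design_precursor(
                    mature, params, seed=rng.randrange(2**31), backend=backend
                )
            except ValueError:
                continue
            matures.append(mature)
            precursors.append(prec)
            break
        else:
            raise RuntimeError(f"could not design precursor #{i}")

    decoy_seqs = []
    for i in range(spec.n_decoys):
        category = "rRNA" if i % 2 == 0 else "tRNA"
        length = rng.randint(140, 220) if category == "rRNA" else rng.randint(70, 90)
        decoy_seqs.append((category, _random_seq(rng, length)))

    # --- place features --------------------------------------------------
    features: list[tuple[str, int]] = [
        ("miRNA", i) for i in range(spec.n_mirnas)
    ] + [("decoy", i) for i in range(spec.n_decoys)]
    placed: list[tuple[int, int]] = []

    def free(start: int, end: int) -> bool:
        gap = spec.min_locus_gap
        return all(end + gap <= s or e + gap <= start for s, e in placed)

    genome_list = list(_random_seq(rng, spec.genome_length))
    locations: dict[tuple[str, int], tuple[int, int, str]] = {}
    for key in features:
        length = (
            len(precursors[key[1]]) if key[0] == "miRNA" else len(decoy_seqs[key[1]][1])
        )
        for _ in range(2000):
            start = rng.randrange(0, spec.genome_length - length)
            if free(start, start + length):
                break
        else:
            raise RuntimeError("feature placement collision after bounded retries")
        placed.append((start, start + length))
        strand = rng.choice("+-")
        seq = precursors[key[1]] if key[0] == "miRNA" else decoy_seqs[key[1]][1]
        if strand == "-":
            seq = revcomp(seq)
        genome_list[start : start + length] = seq
        locations[key] = (start, start + length, strand)
    genome = {chrom: "".join(genome_list)}

    # --- ground-truth records -------------------------------------------
    junk_total = sum(spec.junk_fractions.values())
    mirnas = []
    for i in range(spec.n_mirnas):
        start, end, strand = locations[("miRNA", i)]
        copies = count_occurrences(genome, matures[i])
        if copies != 1:
            raise RuntimeError(
                f"planted mature #{i} occurs {copies}x in the genome"
            )
        baseline = min(
            max(
                math.exp(rng.gauss(spec.baseline_log_tpm_mean, spec.baseline_log_tpm_sigma)),
                spec.min_baseline_tpm,
            ),
            spec.max_baseline_tpm,
        )
        p = baseline * (1.0 - junk_total) / 1e6
        mirnas.append(
            MirnaTruth(
                mirna_id=f"mir-{i + 1:03d}",
                mature=matures[i],
                precursor=precursors[i],
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                is_known=i in known_idx,
                is_de=de_flags[i],
                fold_change=fold_changes[i],
                baseline_tpm=baseline,
                expected_count_control=spec.depth_control * p,
                expected_count_treatment=spec.depth_treatment * p * fold_changes[i],
            )
        )

    decoys = [
        DecoyTruth(
            decoy_id=f"decoy-{i + 1:02d}",
            category=decoy_seqs[i][0],
            chrom=chrom,
            start=locations[("decoy", i)][0],
            end=locations[("decoy", i)][1],
            strand=locations[("decoy", i)][2],
            sequence=decoy_seqs[i][1],
        )
        for i in range(spec.n_decoys)
    ]

    # --- background read pool (unannotated space) ------------------------
    pool: list[tuple[str, int, int, str]] = []
    for _ in range(spec.n_background_positions):
        length = rng.randint(20, 24)
        for _ in range(200):
            start = rng.randrange(0, spec.genome_length - length)
            if free(start, start + length):
                break
        else:
            raise RuntimeError("background placement collision")
        pool.append((chrom, start, start + length, rng.choice("+-")))

    return genome, TruthTable(
        spec=spec, mirnas=mirnas, decoys=decoys, background_pool=pool
    )


def write_genome_fasta(genome: dict[str, str], path) -> None:
    from ._util import write_fasta

    write_fasta(sorted(genome.items()), path)


def write_truth_gff3(truth: TruthTable, path) -> None:
    """1-based inclusive GFF3 of planted loci and decoys."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in truth.mirnas:
            fh.write(
                f"{m.chrom}\tmirflow_sim\tmiRNA_primary_transcript\t{m.start + 1}\t"
                f"{m.end}\t.\t{m.strand}\t.\tID={m.mirna_id}\n"
            )
        for d in truth.decoys:
            fh.write(
                f"{d.chrom}\tmirflow_sim\t{d.category}\t{d.start + 1}\t{d.end}\t.\t"
                f"{d.strand}\t.\tID={d.decoy_id}\n"
            )


def _mirna_probs(
    truth: TruthTable, condition: str, rng, spec: SyntheticSpec | None = None
) -> np.ndarray:
    spec = spec or truth.spec
    junk_total = sum(spec.junk_fractions.values())
    probs = []
    for m in truth.mirnas:
        tpm = m.baseline_tpm
        if condition == "treatment" and m.is_de:
            tpm *= m.fold_change
        if spec.dispersion:
            shape = 1.0 / spec.dispersion
            tpm *= rng.gamma(shape, 1.0 / shape)
        probs.append(tpm * (1.0 - junk_total) / 1e6)
    return np.asarray(probs)


def simulate_library(
    genome: dict[str, str],
    truth: TruthTable,
    condition: str,
    spec: SyntheticSpec | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate one library as ``(id, sequence, quality)`` records.

    Clean reads carry the insert followed by the 3' adaptor, truncated to
    the read length; qualities are constant 'I' (Phred 40).  Junk classes
    are drawn by a single categorical per read at the spec fractions, so
    the record count equals the depth exactly.  Deterministic in
    (spec.seed, condition).
    """
    if condition not in ("control", "treatment"):
        raise ValueError(f"condition must be control/treatment, got {condition!r}")
    spec = spec or truth.spec
    depth = spec.depth_control if condition == "control" else spec.depth_treatment
    if depth <= 0:
        raise ValueError("library depth must be positive")
    cond_idx = 0 if condition == "control" else 1
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, cond_idx]))
    pyrng = random.Random(int(rng.integers(2**31)))

    junk_names = [k for k in JUNK_CLASSES if spec.junk_fractions.get(k, 0) > 0]
    junk_probs = [spec.junk_fractions[k] for k in junk_names]
    mirna_probs = _mirna_probs(truth, condition, rng, spec)
    bg_prob = spec.background_fraction
    decoy_prob = 1.0 - sum(junk_probs) - bg_prob - float(mirna_probs.sum())
    if decoy_prob < spec.decoy_min_fraction:
        raise ValueError(
            "planted abundances leave too little probability mass for decoys; "
            "reduce abundances or background/junk fractions"
        )

    names = junk_names + [m.mirna_id for m in truth.mirnas] + ["background", "decoy"]
    probs = np.array(junk_probs + list(mirna_probs) + [bg_prob, decoy_prob])
    draws = rng.choice(len(names), size=depth, p=probs / probs.sum())

    chrom_seq = {c: s for c, s in genome.items()}
    adaptor = to_dna(spec.adaptor3)
    pad = "A" * spec.read_length
    qual = "I" * spec.read_length
    mature_by_id = {m.mirna_id: m.mature for m in truth.mirnas}
    probe = adaptor[:8]

    def finish(insert: str) -> str:
        return (insert + adaptor + pad)[: spec.read_length]

    records = []
    for i, d in enumerate(draws):
        cls = names[d]
        if cls == "poly_a":
            seq = finish("A" * pyrng.randint(18, 26))
        elif cls == "no_adaptor":
            while True:
                seq = _random_seq(pyrng, spec.read_length)
                if probe not in seq:
                    break
        elif cls == "no_insert":
            seq = finish("")
        elif cls == "too_short":
            seq = finish(_random_seq(pyrng, pyrng.randint(8, 17)))
        elif cls == "low_quality":
            seq = list(finish(_random_seq(pyrng, 22)))
            for j in pyrng.sample(range(spec.read_length), 5):
                seq[j] = "N"
            seq = "".join(seq)
        elif cls == "background":
            chrom, s, e, strand = truth.background_pool[
                pyrng.randrange(len(truth.background_pool))
            ]
            insert = chrom_seq[chrom][s:e]
            if strand == "-":
                insert = revcomp(insert)
            seq = finish(insert)
        elif cls == "decoy":
            dec = truth.decoys[pyrng.randrange(len(truth.decoys))]
            flen = pyrng.randint(18, 28)
            off = pyrng.randrange(0, len(dec.sequence) - flen)
            seq = finish(dec.sequence[off : off + flen])
        else:  # a planted miRNA
            seq = finish(mature_by_id[cls])
        records.append((f"{condition}_{i + 1}", seq, qual))
    return records


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for ident, seq, qual in records:
            fh.write(f"@{ident}\n{seq}\n+\n{qual}\n")


_TRUTH_COLUMNS = [
    "record_type",
    "record_id",
    "chrom",
    "start",
    "end",
    "strand",
    "sequence",
    "precursor",
    "is_known",
    "is_de",
    "fold_change",
    "baseline_tpm",
    "expected_count_control",
    "expected_count_treatment",
]


def truth_to_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for m in truth.mirnas:
        rows.append(
            (
                "miRNA",
                m.mirna_id,
                m.chrom,
                m.start,
                m.end,
                m.strand,
                m.mature,
                m.precursor,
                m.is_known,
                m.is_de,
                m.fold_change,
                m.baseline_tpm,
                m.expected_count_control,
                m.expected_count_treatment,
            )
        )
    for d in truth.decoys:
        rows.append(
            (d.category, d.decoy_id, d.chrom, d.start, d.end, d.strand, d.sequence,
             "", False, False, 1.0, 0.0, 0.0, 0.0)
        )
    for j, (chrom, s, e, strand) in enumerate(truth.background_pool, start=1):
        rows.append(
            ("background", f"bg-{j:03d}", chrom, s, e, strand, "", "",
             False, False, 1.0, 0.0, 0.0, 0.0)
        )
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def emit_truth(truth: TruthTable, path) -> None:
    """Write the ground truth as TSV; round-trips losslessly."""
    try:
        truth_to_frame(truth).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write truth table to {path}: {exc}") from exc


def load_truth(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"cannot read truth table from {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=_TRUTH_COLUMNS)
    for col in ("sequence", "precursor"):
        df[col] = df[col].fillna("").astype(str)
    return df


def simulate_ct_table(
    true_log2fc: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table consistent with given true log2 fold changes.

    The treatment dCt shifts by -log2fc relative to control (ddCt
    convention: a doubling lowers Ct by one cycle), with Gaussian replicate
    noise on both target and reference channels.
    """
    rng = random.Random(seed)
    rows = []
    for target in sorted(true_log2fc):
        base_dct = rng.uniform(2.0, 10.0)
        for cond in ("control", "treatment"):
            shift = -true_log2fc[target] if cond == "treatment" else 0.0
            for rep in range(1, n_replicates + 1):
                ct_ref = 20.0 + rng.gauss(0.0, noise_sd)
                dct = base_dct + shift + rng.gauss(0.0, noise_sd)
                rows.append(
                    (f"{cond}_{rep}", cond, target, ct_ref + dct, ct_ref)
                )
    return pd.DataFrame(
        rows, columns=["sample", "condition", "target", "ct_target", "ct_reference"]
    )
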