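"""End-to-end orchestration: reads -> clean tags -> annotation -> known and
novel miRNA counts -> differential expression, plus truth-based scoring of
synthetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotate as ann
from . import diffexpr as de
from . import novel as nv
from . import preprocess as pp
from . import simdata as sim

CONDITIONS = ("control", "treatment")


@dataclass
class PipelineResult:
    readsets: dict[str, pp.CleanReadSet]
    annotations: dict[str, list[ann.TagAnnotation]]
    tallies: dict[str, pd.DataFrame]
    known_counts: dict[str, dict[str, int]]
    novel: list[nv.NovelMiRNA]
    expression: pd.DataFrame
    totals: de.LibraryTotals
    novel_id_by_mature: dict[str, str] = field(default_factory=dict)


def _build_tracks(truth: sim.TruthTable) -> ann.AnnotationTracks:
    tracks = ann.AnnotationTracks()
    for d in truth.decoys:
        tracks.add_feature(d.category, d.chrom, d.start, d.end, d.strand)
    return tracks


def run_two_library_analysis(
    reads_by_condition: dict[str, list[tuple[str, str, str]]],
    genome: dict[str, str],
    tracks: ann.AnnotationTracks,
    catalog: ann.MatureCatalog | None,
    cleaning: pp.CleaningConfig,
    params: nv.NovelPredictionParams = nv.NovelPredictionParams(),
    min_novel_support: int = 5,
    backend: str = "vienna",
    de_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the full two-library analysis on in-memory reads.

    ``reads_by_condition`` maps 'control'/'treatment' to (id, seq, qual)
    records (use :func:`mirflow.preprocess.iter_fastq` for files).
    """
    index = ann.GenomeIndex(genome)
    readsets, annotations, tallies, known_counts = {}, {}, {}, {}
    for cond in CONDITIONS:
        rs = pp.clean_reads(reads_by_condition[cond], cleaning)
        readsets[cond] = rs
        tags = pp.mirna_tags(rs, cleaning)
        annotations[cond] = ann.annotate_library(tags, index, tracks, catalog)
        tallies[cond] = ann.tally_categories(
            annotations[cond],
            unique_total=len(rs.tags),
            read_total=rs.total_clean,
        )
        known_counts[cond] = ann.known_mirna_counts(annotations[cond])

    # unannotated, genome-mapped tags from both libraries feed novel search
    tag_counts: dict[str, dict[str, int]] = {}
    for cond in CONDITIONS:
        for a in annotations[cond]:
            if a.category == "unannotated" and a.mapped:
                tag_counts.setdefault(a.sequence, {})[cond] = a.count
    novel = nv.predict_novel(
        tag_counts, index, params, min_support=min_novel_support, backend=backend
    )

    rows = []
    known_ids = sorted(set(known_counts["control"]) | set(known_counts["treatment"]))
    for mid in known_ids:
        rows.append(
            (
                mid,
                known_counts["control"].get(mid, 0),
                known_counts["treatment"].get(mid, 0),
            )
        )
    for nov in novel:
        rows.append(
            (nov.mirna_id, nov.counts.get("control", 0), nov.counts.get("treatment", 0))
        )
    counts = pd.DataFrame(rows, columns=["mirna_id", "x", "y"])
    totals = de.LibraryTotals(
        n1=readsets["control"].total_clean, n2=readsets["treatment"].total_clean
    )
    expression = de.differential_expression(counts, totals, **(de_kwargs or {}))
    return PipelineResult(
        readsets=readsets,
        annotations=annotations,
        tallies=tallies,
        known_counts=known_counts,
        novel=novel,
        expression=expression,
        totals=totals,
        novel_id_by_mature={nov.mature: nov.mirna_id for nov in novel},
    )


def run_synthetic_study(
    spec: sim.SyntheticSpec,
    params: nv.NovelPredictionParams = nv.NovelPredictionParams(),
    backend: str = "vienna",
    min_novel_support: int = 5,
    de_kwargs: dict | None = None,
) -> tuple[PipelineResult, sim.TruthTable]:
    """Simulate a two-condition study and run the full analysis on it."""
    genome, truth = sim.build_genome(spec, params, backend=backend)
    reads = {
        cond: sim.simulate_library(genome, truth, cond) for cond in CONDITIONS
    }
    cleaning = pp.CleaningConfig(adaptor3=spec.adaptor3, adaptor5=spec.adaptor5)
    catalog_entries = truth.known_catalog()
    catalog = ann.MatureCatalog(catalog_entries) if catalog_entries else None
    result = run_two_library_analysis(
        reads,
        genome,
        _build_tracks(truth),
        catalog,
        cleaning,
        params,
        min_novel_support=min_novel_support,
        backend=backend,
        de_kwargs=de_kwargs,
    )
    return result, truth


def score_against_truth(
    result: PipelineResult, truth: sim.TruthTable
) -> dict[str, float]:
    """Truth-based performance metrics of one synthetic run.

    Novel recall/precision compare predicted precursor loci against
    planted novel (not-in-catalog) loci: a prediction is a true positive
    when its locus overlaps a planted precursor on the same strand.  DE
    recall counts planted DE miRNAs (known or novel) whose call matches
    the planted direction; the false-call rate counts planted non-DE
    miRNAs called up or down.
    """
    planted_novel = truth.novel_mirnas()
    predicted = result.novel

    def overlaps(m: sim.MirnaTruth, nov: nv.NovelMiRNA) -> bool:
        c = nov.candidate
        return (
            c.chrom == m.chrom
            and c.strand == m.strand
            and c.start < m.end
            and c.end > m.start
        )

    tp_truth = {
        m.mirna_id
        for m in planted_novel
        if any(overlaps(m, nov) for nov in predicted)
    }
    tp_pred = sum(
        1 for nov in predicted if any(overlaps(m, nov) for m in planted_novel)
    )
    novel_recall = len(tp_truth) / len(planted_novel) if planted_novel else 1.0
    novel_precision = tp_pred / len(predicted) if predicted else 1.0

    calls: dict[str, str] = {}
    expr = result.expression.set_index("mirna_id")
    for m in truth.mirnas:
        if m.is_known:
            row_id = m.mirna_id
        else:
            row_id = result.novel_id_by_mature.get(m.mature)
        calls[m.mirna_id] = (
            str(expr.loc[row_id, "call"]) if row_id in expr.index else "missing"
        )

    de_planted = [m for m in truth.mirnas if m.is_de]
    non_de = [m for m in truth.mirnas if not m.is_de]
    correct = sum(
        1
        for m in de_planted
        if calls[m.mirna_id] == ("up" if m.fold_change > 1 else "down")
    )
    false_calls = sum(1 for m in non_de if calls[m.mirna_id] in ("up", "down"))
    return {
        "novel_recall": novel_recall,
        "novel_precision": novel_precision,
        "n_novel_predicted": float(len(predicted)),
        "de_recall": correct / len(de_planted) if de_planted else 1.0,
        "false_call_rate": false_calls / len(non_de) if non_de else 0.0,
        "n_known_identified": float(
            len(set(result.known_counts["control"]) | set(result.known_counts["treatment"]))
        ),
    }
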