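import pandas as pd
import pytest

from mirflow._util import revcomp
from mirflow.simdata import (
    TruthTable,
    build_genome,
    count_occurrences,
    emit_truth,
    load_truth,
    simulate_library,
    truth_to_frame,
    write_fastq,
    write_genome_fasta,
)
from conftest import small_spec, vary


class TestSpecValidation:
    def test_junk_fractions_bounded(self):
        with pytest.raises(ValueError):
            small_spec(junk_fractions={"poly_a": 0.7, "no_adaptor": 0.4})
        with pytest.raises(ValueError):
            small_spec(junk_fractions={"poly_a": -0.1})

    def test_depths_positive(self):
        with pytest.raises(ValueError):
            small_spec(depth_control=0)

    def test_fold_changes_positive_and_sized(self):
        with pytest.raises(ValueError):
            small_spec(de_fold_changes=[4.0, 4.0, -1.0, 0.25])
        with pytest.raises(ValueError):
            small_spec(de_fold_changes=[4.0])

    def test_de_counts_bounded(self):
        with pytest.raises(ValueError):
            small_spec(n_mirnas=3, n_known=2, n_de_up=2, n_de_down=2)


class TestBuildGenome:
    def test_truth_row_counts(self, tiny_spec, tiny_study):
        _genome, truth = tiny_study
        assert len(truth.mirnas) == tiny_spec.n_mirnas
        assert len(truth.decoys) == tiny_spec.n_decoys
        assert sum(m.is_known for m in truth.mirnas) == tiny_spec.n_known
        assert sum(m.is_de for m in truth.mirnas) == tiny_spec.n_de_up + tiny_spec.n_de_down

    def test_matures_planted_exactly_once(self, tiny_study):
        genome, truth = tiny_study
        for m in truth.mirnas:
            assert count_occurrences(genome, m.mature) == 1
            assert m.mature in m.precursor

    def test_precursor_sequence_at_recorded_locus(self, tiny_study):
        genome, truth = tiny_study
        for m in truth.mirnas:
            seq = genome[m.chrom][m.start : m.end]
            if m.strand == "-":
                seq = revcomp(seq)
            assert seq == m.precursor

    def test_loci_do_not_overlap(self, tiny_study):
        _genome, truth = tiny_study
        spans = sorted(
            [(m.start, m.end) for m in truth.mirnas]
            + [(d.start, d.end) for d in truth.decoys]
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_genome_fasta_bytes_reproducible(self, tiny_spec, tmp_path):
        paths = []
        for tag in ("a", "b"):
            genome, _ = build_genome(tiny_spec)
            p = tmp_path / f"{tag}.fa"
            write_genome_fasta(genome, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestSimulateLibrary:
    def test_record_count_equals_depth_exactly(self, tiny_spec, tiny_study):
        genome, truth = tiny_study
        recs = simulate_library(genome, truth, "control", tiny_spec)
        assert len(recs) == tiny_spec.depth_control

    def test_fastq_bytes_reproducible(self, tiny_spec, tiny_study, tmp_path):
        genome, truth = tiny_study
        blobs = []
        for tag in ("a", "b"):
            recs = simulate_library(genome, truth, "treatment", tiny_spec)
            p = tmp_path / f"{tag}.fq"
            write_fastq(recs, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_invalid_condition_rejected(self, tiny_study):
        genome, truth = tiny_study
        with pytest.raises(ValueError):
            simulate_library(genome, truth, "mock")

    def test_observed_counts_track_expectations(self):
        """Mean observed/expected ratio over 20 replicates within 5%.

        Uses abundant planted miRNAs (expected count >= 200) so the
        binomial (Poisson-like) sampling noise averages out.
        """
        spec = small_spec(
            seed=23,
            n_mirnas=5,
            n_known=5,
            n_de_up=0,
            n_de_down=0,
            de_fold_changes=[],
            baseline_log_tpm_mean=9.2,  # ~10000 TPM
            baseline_log_tpm_sigma=0.1,
            min_baseline_tpm=8000.0,
            depth_control=30_000,
            background_fraction=0.0,
        )
        genome, truth = build_genome(spec)
        totals = {m.mirna_id: 0.0 for m in truth.mirnas}
        n_rep = 20
        for rep in range(n_rep):
            rep_spec = vary(spec, seed=1000 + rep)
            recs = simulate_library(genome, truth, "control", rep_spec)
            counts = {}
            for _id, seq, _q in recs:
                counts[seq] = counts.get(seq, 0) + 1
            for m in truth.mirnas:
                read = (m.mature + spec.adaptor3 + "A" * spec.read_length)[
                    : spec.read_length
                ]
                totals[m.mirna_id] += counts.get(read, 0)
        for m in truth.mirnas:
            assert m.expected_count_control >= 200
            ratio = totals[m.mirna_id] / n_rep / m.expected_count_control
            assert 0.95 <= ratio <= 1.05, (m.mirna_id, ratio)

    def test_polya_reads_near_planted_fraction(self):
        spec = small_spec(
            seed=31,
            depth_control=10_000,
            junk_fractions={"poly_a": 0.05},
        )
        genome, truth = build_genome(spec)
        recs = simulate_library(genome, truth, "control", spec)
        n_polya = sum(1 for _i, seq, _q in recs if seq.startswith("A" * 18))
        mean, sd = 500, (10_000 * 0.05 * 0.95) ** 0.5
        assert abs(n_polya - mean) <= 4 * sd

    def test_non_de_expectations_equal_across_conditions(self, tiny_study):
        _genome, truth = tiny_study
        for m in truth.mirnas:
            if not m.is_de:
                assert m.expected_count_control == pytest.approx(
                    m.expected_count_treatment
                )
                assert m.fold_change == 1.0


class TestTruthRoundTrip:
    def test_write_read_write_is_lossless(self, tiny_study, tmp_path):
        _genome, truth = tiny_study
        p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
        emit_truth(truth, p1)
        df = load_truth(p1)
        pd.testing.assert_frame_equal(df, truth_to_frame(truth))
        df.to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_truth_round_trips(self, tiny_spec, tmp_path):
        empty = TruthTable(spec=tiny_spec, mirnas=[], decoys=[], background_pool=[])
        p = tmp_path / "empty.tsv"
        emit_truth(empty, p)
        assert p.read_text().count("\n") == 1  # header only
        assert load_truth(p).empty

    def test_non_de_fold_changes_are_exactly_one(self, tiny_study, tmp_path):
        _genome, truth = tiny_study
        p = tmp_path / "t.tsv"
        emit_truth(truth, p)
        df = load_truth(p)
        mirs = df[df["record_type"] == "miRNA"]
        assert (mirs.loc[~mirs["is_de"], "fold_change"] == 1.0).all()

    def test_write_error_carries_path(self, tiny_study):
        _genome, truth = tiny_study
        with pytest.raises(OSError, match="no/such"):
            emit_truth(truth, "/no/such/dir/truth.tsv")
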