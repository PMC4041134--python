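import dataclasses
import random

import pytest

from mirflow._util import revcomp
from mirflow.annotate import GenomeIndex
from mirflow.fold import fold_rna, pair_table
from mirflow.novel import (
    DuplexStats,
    NovelPredictionParams,
    derive_duplex,
    evaluate_candidate,
    extract_candidate_loci,
    fold,
    predict_novel,
)
from mirflow.simdata import design_precursor

PARAMS = NovelPredictionParams()


class TestFold:
    def test_homopolymer_has_no_structure(self):
        for backend in ("vienna", "simple"):
            struct, mfe = fold_rna("A" * 50, backend=backend)
            assert struct == "." * 50
            assert mfe == 0.0

    def test_long_inverted_repeat_is_very_stable(self):
        rng = random.Random(3)
        stem = "".join(rng.choice("ACGT") for _ in range(30))
        seq = stem + "CATCAT" + revcomp(stem)
        for backend in ("vienna", "simple"):
            _, mfe = fold_rna(seq, backend=backend)
            assert mfe <= -18.0, backend

    def test_fold_deterministic(self):
        seq = "GCAUGGCUAGCUAGCUAGCAUCGAUCGGCAUGCAUGCUAGC"
        assert fold(seq) == fold(seq)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold_rna("ACGTXACGTACGTACGTACGT")

    def test_overlong_sequence_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            fold_rna("A" * 1001)

    def test_pair_table_balanced(self):
        pt = pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]
        with pytest.raises(ValueError):
            pair_table("((.)")


class TestDeriveDuplex:
    def test_perfect_stem(self):
        # 22-bp blunt stem, 8-nt loop
        s = "(" * 22 + "." * 8 + ")" * 22
        d = derive_duplex(s, 0, 22)
        assert d.paired_bases == 22
        assert d.max_bulge == 0
        assert d.asymmetry == 0
        assert d.spacing == 8
        assert d.branches == 0
        # star pairing span is 30..51; the 2-nt overhang is clipped at the end
        assert (d.star_start, d.star_end) == (30, 52)

    def test_interior_bulge_on_mature_side(self):
        # mature: 10 paired, 3-nt bulge, 9 paired; star side fully paired
        s = "(" * 10 + "." * 3 + "(" * 9 + "." * 4 + ")" * 19
        d = derive_duplex(s, 0, 22)
        assert d.paired_bases == 19
        assert d.max_bulge == 3
        assert d.asymmetry == 3

    def test_mature_on_loop_has_no_duplex(self):
        d = derive_duplex("." * 52, 10, 22)
        assert d.paired_bases == 0

    def test_mature_on_three_prime_arm(self):
        s = "(" * 22 + "." * 8 + ")" * 22
        d = derive_duplex(s, 30, 22)
        assert d.paired_bases == 22
        # star is upstream; its 3' overhang extends toward the loop
        assert d.star_start == 0
        assert d.spacing == 30 - d.star_end

    def test_mature_outside_precursor_rejected(self):
        with pytest.raises(ValueError):
            derive_duplex("." * 30, 20, 22)

    def test_stray_long_range_pairs_do_not_join_the_star(self):
        # 16 bases pair a compact star; 3 more pair far away: the compact
        # cluster wins and the bulge stays local
        mature = 22
        s = (
            "(" * 3 + "(" * 16 + "..." # mature: 3 stray + 16 real + 3 dots
            + "." * 5
            + ")" * 16          # star for the 16
            + "." * 40
            + ")" * 3           # distant partners of the stray 3
        )
        d = derive_duplex(s, 0, mature)
        assert d.paired_bases == 16
        assert d.star_end - d.star_start <= 19


def _passing_candidate():
    precursor, cand = design_precursor("ACGTACGTGGCATCGATCGATC", PARAMS, seed=5)
    return cand


class TestEvaluate:
    def test_designed_precursor_passes_every_criterion(self):
        cand = _passing_candidate()
        verdict = evaluate_candidate(cand, PARAMS)
        assert verdict.passed and verdict.reasons == ()

    def test_energy_just_above_threshold_fails(self):
        cand = dataclasses.replace(_passing_candidate())
        cand.mfe = -17.5
        verdict = evaluate_candidate(cand, PARAMS)
        assert not verdict.passed
        assert "free_energy" in verdict.reasons

    def test_fifteen_paired_bases_fail(self):
        cand = _passing_candidate()
        cand.duplex = dataclasses.replace(cand.duplex, paired_bases=15)
        verdict = evaluate_candidate(cand, PARAMS)
        assert verdict.reasons == ("min_duplex_pairs",)

    def test_multicopy_tag_fails(self):
        cand = _passing_candidate()
        cand.genome_copies = 21
        assert "genome_copies" in evaluate_candidate(cand, PARAMS).reasons

    def test_fail_lists_every_violation(self):
        cand = _passing_candidate()
        cand.mfe = -1.0
        cand.duplex = DuplexStats(0, 0, paired_bases=3, max_bulge=9, asymmetry=8, spacing=400)
        reasons = set(evaluate_candidate(cand, PARAMS).reasons)
        assert {"free_energy", "spacing", "min_duplex_pairs", "max_bulge", "asymmetry"} <= reasons


class TestCandidateLoci:
    def test_multicopy_tags_excluded(self):
        hits = [("c", i * 1000, "+") for i in range(21)]
        loci = extract_candidate_loci([("A" * 22, hits)], {"c": 50_000}, PARAMS)
        assert loci == []

    def test_window_arithmetic_and_clipping(self):
        reach = PARAMS.flank + PARAMS.max_spacing + PARAMS.max_star_len
        loci = extract_candidate_loci(
            [("G" * 22, [("c", 1000, "+")])], {"c": 50_000}, PARAMS
        )
        assert len(loci) == 2
        spans = sorted((l.start, l.end) for l in loci)
        assert spans == [
            (1000 - reach, 1022 + PARAMS.flank),
            (1000 - PARAMS.flank, 1022 + reach),
        ]

    def test_chromosome_start_clipped(self):
        loci = extract_candidate_loci(
            [("G" * 22, [("c", 3, "+")])], {"c": 800}, PARAMS
        )
        assert all(l.start == 0 for l in loci)
        assert all(l.end <= 800 for l in loci)


@pytest.fixture(scope="module")
def planted(tiny_study):
    genome, truth = tiny_study
    return genome, truth, GenomeIndex(genome)


class TestPredictNovel:
    def test_recovers_expressed_planted_precursors(self, planted):
        genome, truth, index = planted
        tag_counts = {
            m.mature: {"control": 60, "treatment": 60} for m in truth.mirnas
        }
        novel = predict_novel(tag_counts, index, PARAMS)
        found = set()
        for m in truth.mirnas:
            for nov in novel:
                c = nov.candidate
                if c.chrom == m.chrom and c.strand == m.strand and c.start < m.end and c.end > m.start:
                    found.add(m.mirna_id)
        assert len(found) == len(truth.mirnas)

    def test_stacked_tags_merge_into_one_call(self, planted):
        genome, truth, index = planted
        m = truth.mirnas[0]
        # second tag: the mature arm shifted by one genomic base
        if m.strand == "+":
            shifted = genome[m.chrom][m.start + 1 : m.start + 1 + len(m.mature)]
        else:
            shifted = revcomp(genome[m.chrom][m.end - len(m.mature) - 1 : m.end - 1])
        tag_counts = {
            m.mature: {"control": 50},
            shifted: {"control": 20},
        }
        novel = predict_novel(tag_counts, index, PARAMS)
        assert len(novel) == 1
        assert novel[0].mature == m.mature  # most abundant tag defines the arm
        assert novel[0].counts == {"control": 70}

    def test_low_support_tags_ignored(self, planted):
        genome, truth, index = planted
        tag_counts = {truth.mirnas[0].mature: {"control": 2}}
        assert predict_novel(tag_counts, index, PARAMS, min_support=5) == []

    def test_output_is_locus_sorted_and_ids_sequential(self, planted):
        genome, truth, index = planted
        tag_counts = {m.mature: {"control": 30} for m in truth.mirnas}
        novel = predict_novel(tag_counts, index, PARAMS)
        loci = [n.locus for n in novel]
        assert loci == sorted(loci)
        assert [n.mirna_id for n in novel] == [
            f"novel_mir_{i + 1}" for i in range(len(novel))
        ]


class TestDesignContract:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_designed_precursors_pass_with_margin(self, seed):
        rng = random.Random(seed)
        while True:
            mature = "".join(rng.choice("ACGT") for _ in range(22))
            gc = (mature.count("G") + mature.count("C")) / 22
            if 0.4 <= gc <= 0.7:
                break
        precursor, cand = design_precursor(mature, PARAMS, seed=seed)
        assert evaluate_candidate(cand, PARAMS).passed
        assert cand.duplex.paired_bases >= PARAMS.min_duplex_pairs + 2
        assert cand.duplex.max_bulge <= PARAMS.max_bulge - 2
        assert cand.mfe <= PARAMS.max_free_energy - 5

    def test_design_deterministic(self):
        a = design_precursor("ACGTACGTGGCATCGATCGATC", PARAMS, seed=9)[0]
        b = design_precursor("ACGTACGTGGCATCGATCGATC", PARAMS, seed=9)[0]
        assert a == b

    def test_homopolymer_rejected(self):
        with pytest.raises(ValueError):
            design_precursor("A" * 22, PARAMS, seed=0, max_attempts=6)
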