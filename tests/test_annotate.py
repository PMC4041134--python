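import random

import pytest

from mirflow._util import format_percent, revcomp
from mirflow.annotate import (
    AnnotationTracks,
    GenomeIndex,
    MatureCatalog,
    classify_read,
    tally_categories,
)
from mirflow.preprocess import ReadTag
from _oracles import naive_hits


@pytest.fixture(scope="module")
def rng():
    return random.Random(7)


@pytest.fixture(scope="module")
def toy_genome(rng):
    return {"chrA": "".join(rng.choice("ACGT") for _ in range(5000))}


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return GenomeIndex(toy_genome)


class TestGenomeIndex:
    def test_forward_substring_found_at_source(self, toy_genome, toy_index):
        q = toy_genome["chrA"][1200:1222]
        assert ("chrA", 1200, "+") in toy_index.lookup(q)

    def test_reverse_complement_found_on_minus(self, toy_genome, toy_index):
        q = revcomp(toy_genome["chrA"][1200:1222])
        assert ("chrA", 1200, "-") in toy_index.lookup(q)

    def test_substituted_base_absent(self, toy_genome, toy_index):
        q = list(toy_genome["chrA"][300:322])
        q[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[10]]
        q = "".join(q)
        assert toy_index.lookup(q) == naive_hits(toy_genome, q)

    def test_agrees_with_naive_scan_on_random_queries(self, toy_genome, toy_index, rng):
        for _ in range(50):
            start = rng.randrange(0, 4970)
            n = rng.randint(18, 28)
            q = toy_genome["chrA"][start : start + n]
            if rng.random() < 0.5:
                q = revcomp(q)
            assert toy_index.lookup(q) == naive_hits(toy_genome, q)

    def test_duplicated_locus_yields_both_hits(self, rng):
        core = "".join(rng.choice("ACGT") for _ in range(25))
        genome = {"c": "AAAA" + core + "TTTTCCCC" + core + "GGGG"}
        hits = GenomeIndex(genome).lookup(core)
        assert [(c, p) for c, p, s in hits if s == "+"] == [("c", 4), ("c", 37)]

    def test_duplicate_chromosome_rejected(self, tmp_path):
        fa = tmp_path / "dup.fa"
        fa.write_text(">c\nACGTACGTACGTACGTACGT\n>c\nTTTTACGTACGTACGTACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            GenomeIndex.from_fasta(fa)

    def test_query_shorter_than_seed_rejected(self, toy_index):
        with pytest.raises(ValueError, match="shorter"):
            toy_index.lookup("ACGT")


class TestMatureCatalog:
    def test_exact_match_returns_identifier(self):
        cat = MatureCatalog([("mirA", "ACGUACGUACGUACGUACGUAC")])
        assert cat.match("ACGTACGTACGTACGTACGTAC") == ("mirA", ["mirA"])

    @pytest.mark.parametrize("variant", [
        "ACGTACGTACGTACGTACGTA",     # one base shorter
        "ACGTACGTACGTACGTACGTACA",   # one extra terminal base
        "TCGTACGTACGTACGTACGTAC",    # internal substitution
    ])
    def test_isomirs_do_not_match(self, variant):
        cat = MatureCatalog([("mirA", "ACGTACGTACGTACGTACGTAC")])
        assert cat.match(variant) == (None, [])

    def test_tie_broken_by_file_order_with_audit(self):
        cat = MatureCatalog([
            ("mir1", "ACGTACGTACGTACGTAC"),
            ("mir2", "ACGTACGTACGTACGTAC"),
        ])
        first, all_ids = cat.match("ACGTACGTACGTACGTAC")
        assert first == "mir1"
        assert all_ids == ["mir1", "mir2"]

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MatureCatalog([])


def _tracks_with(ftype, chrom, start, end, strand):
    tracks = AnnotationTracks()
    tracks.add_feature(ftype, chrom, start, end, strand)
    return tracks


class TestClassifyRead:
    def test_mature_match_beats_exon_overlap(self, toy_genome, toy_index):
        seq = toy_genome["chrA"][100:122]
        tracks = _tracks_with("exon", "chrA", 50, 200, "+")
        cat = MatureCatalog([("mirX", seq)])
        ann = classify_read(ReadTag(seq, 3), toy_index, tracks, cat)
        assert ann.category == "miRNA"
        assert ann.mapped

    def test_antisense_rrna_overlap_falls_through(self, toy_genome, toy_index):
        seq = toy_genome["chrA"][100:122]
        # feature on minus strand only; the tag hit is on plus
        tracks = _tracks_with("rRNA", "chrA", 90, 140, "-")
        ann = classify_read(ReadTag(seq, 1), toy_index, tracks, None)
        assert ann.category == "unannotated"

    def test_sense_rrna_overlap_is_rrna(self, toy_genome, toy_index):
        seq = toy_genome["chrA"][100:122]
        tracks = _tracks_with("rRNA", "chrA", 90, 140, "+")
        ann = classify_read(ReadTag(seq, 1), toy_index, tracks, None)
        assert ann.category == "rRNA"

    def test_unmapped_unmatched_is_unannotated(self, toy_index):
        ann = classify_read(
            ReadTag("TTTTTTTTTTGGGGGGGGGGCC", 1), toy_index, AnnotationTracks(), None
        )
        assert ann.category == "unannotated"
        assert not ann.mapped

    def test_intron_is_gene_minus_exon(self, toy_genome, toy_index):
        seq = toy_genome["chrA"][300:322]
        tracks = AnnotationTracks()
        tracks.add_feature("gene", "chrA", 100, 600, "+")
        tracks.add_feature("exon", "chrA", 100, 250, "+")
        ann = classify_read(ReadTag(seq, 1), toy_index, tracks, None)
        assert ann.category == "intron_sense"

    def test_exon_antisense(self, toy_genome, toy_index):
        seq = toy_genome["chrA"][300:322]
        tracks = _tracks_with("exon", "chrA", 250, 400, "-")
        ann = classify_read(ReadTag(seq, 1), toy_index, tracks, None)
        assert ann.category == "exon_antisense"


class TestTally:
    @pytest.mark.parametrize("count,total,expected", [
        (5_003_869, 21_668_361, "23.09%"),
        (16_586_059, 21_668_361, "76.55%"),
        (5_618_205, 21_530_509, "26.09%"),
        (16_889_709, 21_530_509, "78.45%"),
        (1_005_187, 21_668_361, "4.64%"),
        (10_112_207, 21_668_361, "46.67%"),
        (3_776_597, 4_505_507, "83.82%"),
    ])
    def test_percent_formatting_matches_printed_table(self, count, total, expected):
        assert format_percent(count, total) == expected

    def test_zero_total_guarded(self):
        with pytest.raises(ValueError):
            format_percent(1, 0)
        with pytest.raises(ValueError):
            tally_categories([], unique_total=0, read_total=0)

    def test_category_partition_sums_to_clean_reads(self, tiny_run):
        result, _truth = tiny_run
        for cond in ("control", "treatment"):
            anns = result.annotations[cond]
            total = sum(a.count for a in anns)
            df = result.tallies[cond].set_index("category")
            cat_sum = df.drop(index="mapped_to_genome")["total"].sum()
            assert cat_sum == total == result.readsets[cond].total_clean

    def test_each_tag_counted_once(self, tiny_run):
        result, _truth = tiny_run
        anns = result.annotations["control"]
        df = result.tallies["control"].set_index("category")
        assert df.drop(index="mapped_to_genome")["unique"].sum() == len(anns)


class TestDecoyRecovery:
    def test_planted_decoys_recovered_in_their_categories(self, tiny_run):
        result, truth = tiny_run
        index_cat = {}
        for a in result.annotations["control"]:
            index_cat[a.sequence] = a.category
        for d in truth.decoys:
            frag = d.sequence[5:28]
            if frag in index_cat:
                assert index_cat[frag] == d.category

    def test_decoy_fragment_classified_by_gff_tracks(self, tiny_study, tmp_path):
        from mirflow.simdata import write_truth_gff3

        genome, truth = tiny_study
        gff = tmp_path / "tracks.gff3"
        write_truth_gff3(truth, gff)
        tracks = AnnotationTracks.from_gff3(gff)
        index = GenomeIndex(genome)
        d = truth.decoys[0]
        frag = d.sequence[3:26]
        ann = classify_read(ReadTag(frag, 2), index, tracks, None)
        assert ann.category == d.category

    def test_malformed_gff_raises(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("chr1\tsrc\n")
        with pytest.raises(ValueError, match="GFF3"):
            AnnotationTracks.from_gff3(bad)
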