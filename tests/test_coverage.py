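"""Coverage binning, transcribed-region detection and relation labelling."""

import numpy as np
import pandas as pd
import pytest

from phagetime.coverage import (
    NcRNACandidate,
    bin_coverage,
    classify_relation,
    detect_transcribed_regions,
    load_published_ncrna_table,
    per_base_depth,
)
from phagetime.io import GeneFeature


def iv(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])


class TestBinning:
    def test_single_read_lands_in_bin_one(self):
        bins = bin_coverage(iv([("phage", 1, 90, "+")]), 1000, 250, "+")
        assert bins[0] == 1 and bins.sum() == 1

    def test_boundary_read_at_251_lands_in_bin_two(self):
        bins = bin_coverage(iv([("phage", 251, 340, "+")]), 1000, 250, "+")
        assert bins.tolist() == [0, 1, 0, 0]

    def test_minus_strand_uses_interval_end_as_five_prime(self):
        # read spanning 200..260 on - strand has its 5' end at 260 -> bin 2
        bins = bin_coverage(iv([("phage", 200, 260, "-")]), 1000, 250, "-")
        assert bins.tolist() == [0, 1, 0, 0]

    def test_conservation_on_random_reads(self, rng):
        n = 5000
        starts = rng.integers(1, 49_000, n)
        ends = starts + rng.integers(50, 120, n)
        strands = rng.choice(["+", "-"], n)
        reads = iv([("phage", s, e, st) for s, e, st in zip(starts, ends, strands)])
        for strand in "+-":
            bins = bin_coverage(reads, 50_000, 250, strand)
            assert bins.sum() == (strands == strand).sum()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            bin_coverage(iv([("phage", 990, 1100, "+")]), 1000)


class TestDetection:
    def gene(self, gid, start, end, strand):
        return GeneFeature(gid, "phage", start, end, strand, organism="phage")

    def test_zero_coverage_gives_empty_list(self):
        depth = np.zeros(5000)
        assert detect_transcribed_regions(depth, "+", [], "phage") == []

    def test_uniform_block_detected(self):
        depth = np.zeros(5000)
        depth[199:500] = 100.0  # bases 200..500
        (region,) = detect_transcribed_regions(
            depth, "-", [self.gene("g1", 1000, 1400, "-")], "phage",
            min_depth=10, min_length=100,
        )
        assert region == (200, 500, 100.0)

    def test_same_strand_gene_explains_run(self):
        depth = np.zeros(5000)
        depth[999:1400] = 50.0
        regions = detect_transcribed_regions(
            depth, "+", [self.gene("g1", 1000, 1400, "+")], "phage"
        )
        assert regions == []
        # same run on the opposite strand is NOT explained
        regions = detect_transcribed_regions(
            depth, "-", [self.gene("g1", 1000, 1400, "+")], "phage"
        )
        assert len(regions) == 1

    def test_merge_gap_and_min_length(self):
        depth = np.zeros(5000)
        depth[100:220] = 20.0
        depth[250:400] = 20.0   # 30-base gap -> merged
        depth[900:950] = 20.0   # 50 bases -> below min_length
        regions = detect_transcribed_regions(
            depth, "+", [], "phage", min_depth=10, min_length=100, merge_gap=50
        )
        assert [(s, e) for s, e, _ in regions] == [(101, 400)]

    def test_raising_min_depth_is_monotone(self, rng):
        depth = rng.gamma(2.0, 10.0, 20_000)
        prev_regions = None
        for md in (5, 10, 20, 40):
            regions = detect_transcribed_regions(
                depth, "+", [], "phage", min_depth=md, min_length=50
            )
            total = sum(e - s + 1 for s, e, _ in regions)
            if prev_regions is not None:
                assert total <= prev_regions
            prev_regions = total


class TestRelation:
    genes = [
        GeneFeature("gA", "phage", 1000, 1899, "+", organism="phage"),
        GeneFeature("gB", "phage", 2000, 2899, "-", organism="phage"),
    ]

    def test_five_prime_third_of_plus_gene(self):
        cand = classify_relation((1000, 1200, "-"), self.genes, "phage")
        assert cand.relation == "antisense_5prime"
        assert cand.related_genes == ("gA",)

    def test_orientation_correctness_on_minus_gene(self):
        # same early coordinates overlap the 3' end of a minus-strand gene
        cand = classify_relation((2000, 2200, "+"), self.genes, "phage")
        assert cand.relation == "antisense_3prime"

    def test_reversing_gene_strand_swaps_labels(self):
        flipped = [
            GeneFeature("gA", "phage", 1000, 1899, "-", organism="phage")
        ]
        cand = classify_relation((1000, 1200, "+"), flipped, "phage")
        assert cand.relation == "antisense_3prime"

    def test_intergenic_with_flanking_pair(self):
        cand = classify_relation((1920, 1980, "+"), self.genes, "phage")
        assert cand.relation == "intergenic"
        assert cand.related_genes == ("gA", "gB")

    def test_multi_gene_overlap(self):
        genes = [
            GeneFeature("gA", "phage", 1000, 1899, "+", organism="phage"),
            GeneFeature("gB", "phage", 1950, 2849, "+", organism="phage"),
        ]
        cand = classify_relation((1700, 2200, "-"), genes, "phage")
        assert cand.relation == "antisense_multi"
        assert cand.related_genes == ("gA", "gB")
        assert cand.per_gene_labels == ("3prime", "5prime")

    def test_region_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            classify_relation((10, 5, "+"), self.genes, "phage")


class TestPerBaseDepth:
    def test_depth_matches_direct_counting(self, rng):
        n = 300
        starts = rng.integers(1, 900, n)
        ends = starts + rng.integers(10, 90, n)
        ends = np.minimum(ends, 1000)
        reads = iv([("c", s, e, "+") for s, e in zip(starts, ends)])
        depth = per_base_depth(reads, 1000, "+")
        direct = np.zeros(1000)
        for s, e in zip(starts, ends):
            direct[s - 1 : e] += 1
        assert np.array_equal(depth, direct)


class TestEndToEnd:
    def test_detector_plus_classifier_reproduce_planted_relations(self, default_sim):
        """With 10 planted ncRNAs (9 antisense, 1 intergenic) the detected
        candidates must carry the planted relation labels."""
        cfg, features, counts, intervals, truth = default_sim
        late = [s.sample_id for s in counts.samples
                if s.time_min in (28, 35, 42, 49)]
        iv_late = intervals[intervals["sample_id"].isin(late)]
        phage_features = [f for f in features if f.contig == "phage"]
        detected = []
        for strand in "+-":
            depth = per_base_depth(iv_late, cfg.phage_genome_len, strand) / len(late)
            for s, e, d in detect_transcribed_regions(
                depth, strand, phage_features, "phage"
            ):
                detected.append(
                    classify_relation((s, e, strand), phage_features, "phage",
                                      mean_expression=d)
                )
        assert len(truth.planted_ncrnas) == 10
        for _c, ps, pe, pstrand, rel in truth.planted_ncrnas:
            (match,) = [
                c for c in detected
                if c.strand == pstrand and c.start <= pe and c.end >= ps
            ]
            assert match.relation == rel
            assert match.mean_expression >= 10


class TestPublishedTable:
    def test_ten_records_nine_antisense_one_intergenic(self):
        table = load_published_ncrna_table()
        assert len(table) == 10
        antisense = table.relation.str.startswith("antisense")
        assert antisense.sum() == 9
        assert (~antisense).sum() == 1
        assert table.loc[~antisense, "name"].tolist() == ["misc_4"]
        assert table.strand.isin(["+", "-"]).all()
        assert (table.end > table.start).all()
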