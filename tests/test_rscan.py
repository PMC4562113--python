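"""r-scan statistics: span computation, extreme ranking, empirical null,
region calling and cross-referencing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hotscan.intervals import Genome, IntervalSet
from hotscan.rscan import (RscanConfig, call_deficient_regions,
                           cross_reference_deficiency, empirical_null,
                           extreme_spans, interhotspot_distances,
                           positions_from_intervals, rscan_lengths)


class TestDistancesAndLengths:
    def test_distances_examples(self):
        assert interhotspot_distances([0, 10, 30, 60, 100]).tolist() == [10, 20, 30, 40]
        assert interhotspot_distances([5, 8]).tolist() == [3]

    def test_unsorted_input_sorted_internally(self):
        assert interhotspot_distances([60, 0, 100, 30, 10]).tolist() == [10, 20, 30, 40]

    @pytest.mark.parametrize("r,expected", [
        (1, [10, 20, 30, 40]),
        (2, [30, 50, 70]),
        (4, [100]),
        (5, []),
    ])
    def test_lengths_examples(self, r, expected):
        assert rscan_lengths([10, 20, 30, 40], r).tolist() == expected

    def test_lengths_equal_position_differences(self, rng):
        pos = np.sort(rng.integers(0, 1_000_000, 200))
        U = np.diff(pos)
        for r in (1, 3, 7, 24):
            assert np.array_equal(rscan_lengths(U, r), pos[r:] - pos[:-r])

    def test_sum_rule_and_monotonicity(self, rng):
        pos = np.sort(rng.integers(0, 1_000_000, 100))
        U = np.diff(pos)
        assert rscan_lengths(U, 1).sum() == pos[-1] - pos[0]
        r1, r2 = rscan_lengths(U, 2), rscan_lengths(U, 3)
        assert (r2 >= r1[: len(r2)]).all()  # non-decreasing in r at fixed i


class TestExtremeSpans:
    def test_ranked_examples(self):
        spans = extreme_spans({"chr1": [0, 10, 40, 110]}, r=2, k_max=2)
        assert spans["length"].tolist() == [100, 40]
        assert spans["k"].tolist() == [1, 2]

    def test_ties_broken_by_chrom_then_start(self):
        spans = extreme_spans({"chr2": [0, 50], "chr1": [100, 150, 200]}, r=1, k_max=3)
        assert spans["length"].tolist() == [50, 50, 50]
        assert spans["chrom"].tolist() == ["chr1", "chr1", "chr2"]
        assert spans["start"].tolist() == [100, 150, 0]

    def test_pooled_matches_full_sort_oracle(self, rng):
        pos = {c: np.sort(rng.integers(0, 10_000_000, n))
               for c, n in (("chr1", 80), ("chr2", 50))}
        r = 3
        oracle = []
        for c, p in pos.items():
            oracle += [int(x) for x in (p[r:] - p[:-r])]
        top = sorted(oracle, reverse=True)[:10]
        spans = extreme_spans(pos, r=r, k_max=10)
        assert spans["length"].tolist() == top

    def test_fewer_than_k_returns_all_ranked(self):
        spans = extreme_spans({"chr1": [0, 5, 30]}, r=1, k_max=10)
        assert len(spans) == 2 and spans["k"].tolist() == [1, 2]


class TestEmpiricalNull:
    def test_deterministic_given_seed(self):
        cfg = RscanConfig(r_max=3, k_max=2, n_null=100, seed=5, null_source="uniform")
        g = Genome({"chr1": 100_000})
        a = empirical_null({"chr1": 20}, cfg, genome=g)
        b = empirical_null({"chr1": 20}, cfg, genome=g)
        assert np.array_equal(a, b, equal_nan=True)

    def test_degenerate_draw_whole_background_gives_p_one(self):
        bg = np.array([0, 100, 350, 900, 2000])
        cfg = RscanConfig(r_max=2, k_max=2, n_null=100, seed=1)
        pos = {"chr1": bg}
        res = call_deficient_regions(pos, cfg, background_by_chrom={"chr1": bg})
        assert (res.spans["p_raw"] == 1.0).all()
        assert len(res.regions) == 0

    def test_background_smaller_than_test_count_rejected(self):
        cfg = RscanConfig(r_max=1, k_max=1, n_null=100, seed=1)
        with pytest.raises(ValueError):
            empirical_null({"chr1": 10}, cfg, background_by_chrom={"chr1": np.arange(5)})

    def test_toy_null_matches_exhaustive_enumeration(self):
        """m_1^(1) distribution of 3-subsets of 6 background positions."""
        bg = np.array([0, 10, 25, 45, 70, 100])
        exact: dict[int, float] = {}
        for sub in combinations(bg, 3):
            m1 = int(max(np.diff(sub)))
            exact[m1] = exact.get(m1, 0.0) + 1 / 20
        cfg = RscanConfig(r_max=1, k_max=1, n_null=2000, seed=7)
        null = empirical_null({"chr1": 3}, cfg, background_by_chrom={"chr1": bg})
        vals = null[:, 0, 0]
        support = set(exact) | set(vals.tolist())
        tv = 0.5 * sum(abs(exact.get(v, 0.0) - float(np.mean(vals == v)))
                       for v in support)
        assert tv < 0.05


class TestRegionCalling:
    def test_equally_spaced_positions_yield_no_calls(self):
        pos = {"chr1": np.arange(0, 1_000_000, 5000)}
        cfg = RscanConfig(r_max=5, k_max=5, n_null=200, seed=2, null_source="uniform")
        res = call_deficient_regions(pos, cfg, genome=Genome({"chr1": 1_000_000}))
        assert len(res.regions) == 0

    def test_implanted_gap_recovered(self):
        rng = np.random.default_rng(8)
        gap = (4_000_000, 4_300_000)
        left = rng.integers(0, gap[0], 800)
        right = rng.integers(gap[1], 10_000_000, 1200)
        pos = {"chr1": np.sort(np.concatenate([left, right]))}
        cfg = RscanConfig(n_null=500, seed=3, null_source="uniform")
        res = call_deficient_regions(pos, cfg, genome=Genome({"chr1": 10_000_000}))
        assert len(res.regions) >= 1
        best = max(res.regions, key=lambda r: min(r.end, gap[1]) - max(r.start, gap[0]))
        ov = min(best.end, gap[1]) - max(best.start, gap[0])
        assert ov / (gap[1] - gap[0]) > 0.9
        assert ov / (best.end - best.start) > 0.9

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(9)
        pos = {"chr1": np.sort(rng.integers(0, 5_000_000, 500))}
        cfg = RscanConfig(r_max=6, k_max=4, n_null=200, seed=4, null_source="uniform")
        res = call_deficient_regions(pos, cfg, genome=Genome({"chr1": 5_000_000}))
        df = res.spans.sort_values("p_raw")
        assert df["p_adj"].is_monotonic_increasing
        assert ((df["p_raw"] > 0) & (df["p_raw"] <= 1)).all()

    def test_gap_annotations_remove_overlapping_regions(self):
        rng = np.random.default_rng(8)
        gap = (4_000_000, 4_300_000)
        pos = {"chr1": np.sort(np.concatenate([
            rng.integers(0, gap[0], 800), rng.integers(gap[1], 10_000_000, 1200)]))}
        cfg = RscanConfig(n_null=500, seed=3, null_source="uniform")
        anns = IntervalSet("gaps", pd.DataFrame(
            [("chr1", gap[0], gap[1])], columns=["chrom", "start", "end"]))
        res = call_deficient_regions(pos, cfg, genome=Genome({"chr1": 10_000_000}),
                                     gap_annotations=anns)
        assert res.n_removed_gap_overlap >= 1
        for region in res.regions:
            assert region.end <= gap[0] or region.start >= gap[1]

    def test_empty_test_set_returns_empty_result(self):
        cfg = RscanConfig(n_null=100, seed=1, null_source="uniform")
        res = call_deficient_regions({}, cfg, genome=Genome({"chr1": 1000}))
        assert len(res.regions) == 0 and res.spans.empty


class TestCrossReference:
    def test_density_flags(self, interval_factory):
        genome = Genome({"chr1": 10_000_000})
        starts = np.arange(0, 10_000_000, 10_000)  # 1000 sites -> 100/Mb
        sites = IntervalSet("sites", pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + 100}))
        regions = interval_factory("reg", [("chr1", 0, 1_000_000),        # avg density
                                           ("chr1", 5_000_200, 5_009_800)])  # 0 sites
        df = cross_reference_deficiency(regions, sites, genome)
        assert df["truly_deficient"].tolist() == [True, False]
        assert df["n_sites"].iloc[1] == 0

    def test_generator_truth_all_regions_site_dense(self, default_truth,
                                                    default_classified):
        """Regions called from in-vivo depletion keep normal site density."""
        t = default_truth
        in_vivo = default_classified.sites[default_classified.sites["status"] == "in_vivo"]
        pos = positions_from_intervals(IntervalSet("v", in_vivo))
        bg = positions_from_intervals(t.sites)
        cfg = RscanConfig(n_null=300, seed=5)
        res = call_deficient_regions(pos, cfg, background_by_chrom=bg)
        df = cross_reference_deficiency(res.regions, t.sites, t.config.genome_obj)
        if len(df):
            assert df["truly_deficient"].all()
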