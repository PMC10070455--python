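"""Loop calling, set algebra vs brute force, APA, insulation, CTCF, regioneR-style test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rewire3d import loops_tads as lt
from rewire3d import synthetic_data as sd
from conftest import random_loops_frame
from oracles import brute_force_anchor_clusters, brute_force_loop_partition


class TestCallLoops:
    def test_planted_loops_recovered(self):
        rng = np.random.default_rng(17)
        signs = sd.checkerboard_signs(1000, 40)
        loops = sd.random_loop_positions(15, 1000, rng, boost=3.0, signs=signs)
        spec = sd.SimulationSpec(n_bins=1000, depth=7e5, compartment_effect=0.4,
                                 loop_list=loops, seed=23)
        m, _, truth = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        calls = lt.call_loops(m)
        truthset = [(i, j) for i, j, _ in truth.loops_pr]
        called = list(zip(calls["bin1"].astype(int), calls["bin2"].astype(int)))
        recall = np.mean([any(abs(a - i) <= 1 and abs(b - j) <= 1 for a, b in called)
                          for i, j in truthset])
        precision = np.mean([any(abs(a - i) <= 1 and abs(b - j) <= 1
                                 for i, j in truthset) for a, b in called])
        assert recall >= 0.85
        assert precision >= 0.85

    def test_null_map_rarely_calls(self):
        n_seeds, with_calls = 20, 0
        for s in range(n_seeds):
            spec = sd.SimulationSpec(n_bins=300, depth=3e5, compartment_effect=0.0,
                                     seed=500 + s)
            m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
            if len(lt.call_loops(m)) > 0:
                with_calls += 1
        assert with_calls <= 1  # >= 95% of seeds produce zero calls

    def test_localization_within_one_bin(self):
        spec = sd.SimulationSpec(n_bins=300, depth=5e5, compartment_effect=0.0,
                                 loop_list=[(100, 104, 4.0)], seed=9)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        calls = lt.call_loops(m)
        assert len(calls) >= 1
        d = np.abs(calls["bin1"] - 100) + np.abs(calls["bin2"] - 104)
        assert d.min() <= 2

    def test_oversized_donut_rejected(self):
        spec = sd.SimulationSpec(n_bins=30, depth=1e4, compartment_effect=0.0, seed=1)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        with pytest.raises(ValueError):
            lt.call_loops(m, donut_radius_bins=40)


class TestLoopSetAlgebra:
    def _frame(self, pairs, resolution=10_000):
        df = pd.DataFrame(pairs, columns=["bin1", "bin2"])
        df["a1_start"] = df["bin1"] * resolution
        df["a1_end"] = (df["bin1"] + 1) * resolution
        df["a2_start"] = df["bin2"] * resolution
        df["a2_end"] = (df["bin2"] + 1) * resolution
        df["size"] = (df["bin2"] - df["bin1"]) * resolution
        return df

    def test_one_bin_flank_is_common(self):
        sets, counts = lt.classify_loop_sets(self._frame([(100, 150)]),
                                             self._frame([(101, 150)]), 10_000)
        assert counts["common_pr"] == 1 and counts["common_cr"] == 1
        assert counts["pr_specific"] == 0 and counts["cr_specific"] == 0

    def test_two_bins_apart_is_specific(self):
        sets, counts = lt.classify_loop_sets(self._frame([(100, 150)]),
                                             self._frame([(102, 150)]), 10_000)
        assert counts["common_pr"] == 0
        assert counts["pr_specific"] == 1 and counts["cr_specific"] == 1

    def test_partition_counts_reconcile(self):
        rng = np.random.default_rng(3)
        pr = random_loops_frame(rng, 120, 800)
        cr = random_loops_frame(rng, 150, 800)
        _, counts = lt.classify_loop_sets(pr, cr, 10_000)
        assert counts["pr_total"] == counts["pr_specific"] + counts["common_pr"]
        assert counts["cr_total"] == counts["cr_specific"] + counts["common_cr"]

    def test_matches_brute_force(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pr = random_loops_frame(rng, 60, 400)
            cr = random_loops_frame(rng, 70, 400)
            sets, counts = lt.classify_loop_sets(pr, cr, 10_000, flank_bins=1)
            bf_pr, bf_cr = brute_force_loop_partition(pr, cr, 10_000)
            assert counts["common_pr"] == bf_pr.sum()
            assert counts["common_cr"] == bf_cr.sum()


class TestAnchorSets:
    def _frame(self, pairs):
        return TestLoopSetAlgebra._frame(self, pairs)

    def test_shared_anchor_common_other_specific(self):
        # a CR-specific loop sharing anchor 150 with a common loop: the shared
        # anchor is common, the CR loop's other anchor CR-specific
        pr = self._frame([(100, 150)])
        cr = self._frame([(100, 150), (150, 200)])
        anchors = lt.classify_anchor_sets(pr, cr, 10_000)
        by_start = {int(r["start"]) // 10_000: r["category"] for _, r in anchors.iterrows()}
        assert by_start[100] == "common"
        assert by_start[150] == "common"
        assert by_start[200] == "CR-specific"

    def test_abutting_anchors_merge(self):
        pr = self._frame([(100, 101), (300, 400)])
        anchors = lt.classify_anchor_sets(pr, self._frame([(300, 400)]), 10_000)
        merged = anchors[anchors["start"] == 100 * 10_000]
        assert len(merged) == 1
        assert int(merged.iloc[0]["end"]) == 102 * 10_000

    def test_categories_tile_without_overlap(self):
        rng = np.random.default_rng(7)
        anchors = lt.classify_anchor_sets(random_loops_frame(rng, 80, 600),
                                          random_loops_frame(rng, 80, 600), 10_000)
        s = anchors.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_matches_brute_force(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            pr = random_loops_frame(rng, 40, 300)
            cr = random_loops_frame(rng, 40, 300)
            res = lt.classify_anchor_sets(pr, cr, 10_000, flank_bins=1)
            got = sorted((int(r["start"]), int(r["end"]),
                          r["category"]) for _, r in res.iterrows())
            anchors = []
            for df, cond in ((pr, "PR"), (cr, "CR")):
                for _, r in df.iterrows():
                    anchors.append((int(r["a1_start"]), int(r["a1_end"]), cond))
                    anchors.append((int(r["a2_start"]), int(r["a2_end"]), cond))
            expected = brute_force_anchor_clusters(anchors, 10_000)
            assert got == expected

    def test_excluded_regions_removed_first(self):
        pr = self._frame([(100, 150)])
        cr = self._frame([(100, 200)])
        excl = [(150 * 10_000, 151 * 10_000)]
        anchors = lt.classify_anchor_sets(pr, cr, 10_000, excluded_regions=excl)
        assert 150 * 10_000 not in set(anchors["start"])


class TestAPA:
    def test_planted_boost_ratio(self):
        rng = np.random.default_rng(3)
        loops = sd.random_loop_positions(15, 1000, rng, distance_range=(15, 30),
                                         boost=3.0)
        spec = sd.SimulationSpec(n_bins=1000, depth=2e6, compartment_effect=0.0,
                                 loop_list=loops, seed=6)
        m, _, truth = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        frame = pd.DataFrame([(i, j) for i, j, _ in truth.loops_pr],
                             columns=["bin1", "bin2"])
        _, ratio = lt.apa(m, frame, window_bins=10)
        assert ratio == pytest.approx(3.0, abs=0.3)

    def test_random_pixels_ratio_near_one(self):
        spec = sd.SimulationSpec(n_bins=1000, depth=2e6, compartment_effect=0.0, seed=8)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        rng = np.random.default_rng(5)
        b1 = rng.integers(100, 800, 20)
        frame = pd.DataFrame({"bin1": b1, "bin2": b1 + rng.integers(15, 30, 20)})
        _, ratio = lt.apa(m, frame, window_bins=10)
        assert ratio == pytest.approx(1.0, abs=0.2)

    def test_window_one_exact_pixel_ratio(self):
        spec = sd.SimulationSpec(n_bins=200, depth=4e5, compartment_effect=0.0, seed=2)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        from rewire3d.contact_map import observed_over_expected
        oe, _ = observed_over_expected(m)
        frame = pd.DataFrame({"bin1": [50], "bin2": [80]})
        agg, ratio = lt.apa(m, frame, window_bins=1)
        assert ratio == pytest.approx(oe[50, 80] / oe[51, 79])


class TestInsulation:
    def test_internal_boundary_found(self):
        spec = sd.SimulationSpec(n_bins=400, depth=6e5, compartment_effect=0.0,
                                 tad_list=[(100, 150, 3.0), (150, 220, 3.0)], seed=5)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        track = lt.insulation_track(m, window_bins=8)
        b = lt.call_tad_boundaries(track, delta_threshold=0.3, min_separation_bins=5)
        internal = b[(b["bin"] >= 149) & (b["bin"] <= 151)]
        assert len(internal) == 1
        assert len(b) == 1

    def test_uniform_map_no_boundaries(self):
        spec = sd.SimulationSpec(n_bins=400, depth=6e5, compartment_effect=0.0, seed=9)
        m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
        track = lt.insulation_track(m, window_bins=8)
        assert len(lt.call_tad_boundaries(track, 0.3, 5)) == 0

    def test_boundary_strength_monotone_in_boost(self):
        strengths = []
        for boost in (2.0, 3.0, 4.0):
            spec = sd.SimulationSpec(n_bins=400, depth=6e5, compartment_effect=0.0,
                                     tad_list=[(100, 150, boost), (150, 220, boost)],
                                     seed=5)
            m, _, _ = sd.simulate_condition_pair(spec, sd.RewiringSpec(seed=1))
            track = lt.insulation_track(m, window_bins=8)
            b = lt.call_tad_boundaries(track, 0.2, 5)
            strengths.append(b[(b["bin"] >= 148) & (b["bin"] <= 152)]["strength"].iloc[0])
        assert strengths[0] < strengths[1] < strengths[2]

    def test_tad_splits_increase_boundary_count(self, small_pair):
        spec = sd.SimulationSpec(n_bins=400, depth=8e5, compartment_effect=0.0,
                                 tad_list=[(80, 200, 3.0)], seed=14)
        rew = sd.RewiringSpec(tad_splits=[140], seed=2)
        m_pr, m_cr, _ = sd.simulate_condition_pair(spec, rew)
        b_pr = lt.call_tad_boundaries(lt.insulation_track(m_pr, 8), 0.25, 5)
        b_cr = lt.call_tad_boundaries(lt.insulation_track(m_cr, 8), 0.25, 5)
        assert len(b_cr) > len(b_pr)
        assert any(abs(int(x) - 140) <= 2 for x in b_cr["bin"])


class TestCTCF:
    def _motifs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])

    def _anchors(self, ivs):
        return pd.DataFrame(ivs, columns=["start", "end"])

    def test_anchor_categories(self):
        motifs = self._motifs([
            ("c", 1000, 1019, "m1", 0, "+"), ("c", 2000, 2019, "m2", 0, "-"),
            ("c", 2500, 2519, "m3", 0, "+"), ("c", 50_000, 50_019, "m4", 0, "+"),
        ])
        anchors = self._anchors([(0, 10_000), (60_000, 70_000), (100_000, 110_000)])
        out = lt.annotate_ctcf(anchors, motifs, resolution=10_000)
        assert list(out["ctcf_category"]) == ["multiple", "adjacent-only", "none"]

    def test_single_motif_category(self):
        motifs = self._motifs([("c", 1000, 1019, "m1", 0, "+")])
        out = lt.annotate_ctcf(self._anchors([(0, 10_000)]), motifs, 10_000)
        assert list(out["ctcf_category"]) == ["single"]

    @pytest.mark.parametrize("left,right,expected", [
        ("+", "-", "convergent"), ("-", "+", "divergent"),
        ("+", "+", "tandem"), ("-", "-", "tandem"),
    ])
    def test_convergence_classes(self, left, right, expected):
        loops = pd.DataFrame({"a1_start": [0], "a1_end": [10_000],
                              "a2_start": [50_000], "a2_end": [60_000]})
        motifs = self._motifs([("c", 5_000, 5_019, "m1", 0, left),
                               ("c", 55_000, 55_019, "m2", 0, right)])
        assert lt.loop_convergence(loops, motifs, 10_000).iloc[0] == expected

    def test_one_sided_and_none(self):
        loops = pd.DataFrame({"a1_start": [0], "a1_end": [10_000],
                              "a2_start": [50_000], "a2_end": [60_000]})
        one = self._motifs([("c", 5_000, 5_019, "m1", 0, "+")])
        assert lt.loop_convergence(loops, one, 10_000).iloc[0] == "one-sided"
        empty = self._motifs([])
        assert lt.loop_convergence(loops, empty, 10_000).iloc[0] == "none"


class TestPermutationEnrichment:
    def test_query_equals_reference_minimal_p(self):
        # sparse regions: no circular shift reproduces the full self-overlap
        regions = [(i * 2_000_000, i * 2_000_000 + 1_000) for i in range(5)]
        z, p, direction = lt.permutation_enrichment(regions, regions, 10_000_000,
                                                    n_perm=199, seed=1)
        assert direction == "enriched"
        assert p == pytest.approx(1.0 / 200.0)

    def test_empty_reference_reports_depleted(self):
        regions = [(0, 1000), (5000, 6000)]
        z, p, direction = lt.permutation_enrichment(regions, [], 100_000,
                                                    n_perm=100, seed=1)
        assert direction == "depleted"

    def test_null_p_uniform(self):
        """Independent query/reference: enrichment p below 0.05 about 5% of
        the time, and the p distribution is consistent with U(0,1)."""
        ps = []
        for rep in range(200):
            r = np.random.default_rng(3000 + rep)
            L = 2_000_000
            q = [(int(s), int(s) + 5000) for s in sorted(r.integers(0, L - 10_000, 60))]
            f = [(int(s), int(s) + 5000) for s in sorted(r.integers(0, L - 10_000, 60))]
            z, p, d = lt.permutation_enrichment(q, f, L, n_perm=199, seed=rep)
            ps.append(p if d == "enriched" else 1 - p + 1.0 / 200)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
        enriched_rate = np.mean([p < 0.05 for p in ps])
        assert 0.02 <= enriched_rate <= 0.08


class TestLoopSizeStats:
    def test_median(self):
        df = pd.DataFrame({"size": [100_000, 200_000, 300_000]})
        medians, hist, _ = lt.loop_size_stats({"common": df})
        assert medians["common"] == 200_000
        assert hist["common"] == {"<100kb": 0, "100kb-1Mb": 3, ">1Mb": 0}

    def test_identical_samples_p_one(self):
        df = pd.DataFrame({"size": [100_000, 200_000, 300_000]})
        _, _, p = lt.loop_size_stats({"a": df, "b": df.copy()}, compare=("a", "b"))
        assert p == 1.0

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(11)
        hits = 0
        for rep in range(20):
            a = pd.DataFrame({"size": rng.normal(250_000, 50_000, 500)})
            b = pd.DataFrame({"size": rng.normal(300_000, 50_000, 500)})
            _, _, p = lt.loop_size_stats({"a": a, "b": b}, compare=("a", "b"))
            hits += p < 0.01
        assert hits >= 19

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError):
            lt.loop_size_stats({"empty": pd.DataFrame({"size": []})})
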