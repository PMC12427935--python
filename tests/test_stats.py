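"""Enrichment Z-test, Mann-Whitney U, set overlap, cHet comparison, qPCR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import damidte as d
from damidte.stats import BoxStats


def universe(n_ltr, n_other):
    return pd.DataFrame(
        {
            "te_name": [f"L{i}" for i in range(n_ltr)]
            + [f"O{i}" for i in range(n_other)],
            "family_class": ["LTR"] * n_ltr + ["LINE"] * n_other,
        }
    )


class TestClassEnrichmentZtest:
    def test_same_composition_gives_null(self):
        uni = universe(5, 5)
        res = d.class_enrichment_ztest(["L0", "O0"], uni, "LTR")
        assert res.z == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_statistic(self):
        # selected 10/10 LTR, universe 50/100 LTR
        uni = universe(50, 50)
        selected = [f"L{i}" for i in range(10)]
        res = d.class_enrichment_ztest(selected, uni, "LTR")
        p_pool = (10 + 50) / (10 + 100)
        se = math.sqrt(p_pool * (1 - p_pool) * (1 / 10 + 1 / 100))
        z_expected = (1.0 - 0.5) / se
        assert res.z == pytest.approx(z_expected, abs=1e-12)
        assert res.p_value == pytest.approx(2 * sps.norm.sf(z_expected), abs=1e-12)
        assert res.z > 0  # enrichment means positive z

    def test_depletion_gives_negative_z(self):
        uni = universe(50, 50)
        res = d.class_enrichment_ztest([f"O{i}" for i in range(10)], uni, "LTR")
        assert res.z < 0

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            d.class_enrichment_ztest([], universe(5, 5), "LTR")

    def test_selection_outside_universe_errors(self):
        with pytest.raises(ValueError, match="not in universe"):
            d.class_enrichment_ztest(["nope"], universe(5, 5), "LTR")


class TestOverlapSets:
    def _series(self, values):
        return pd.Series(values)

    def test_disjoint_sets_jaccard_zero(self):
        a = self._series({"x": 2.0, "y": 0.0, "z": 0.0})
        b = self._series({"x": 0.0, "y": -2.0, "z": 0.0})
        res = d.overlap_sets(a, b)
        assert res.set_up == {"x"} and res.set_down == {"y"}
        assert res.intersection == set()
        assert res.jaccard == 0.0

    def test_identical_sets_jaccard_one(self):
        a = self._series({"x": 2.0, "y": 2.0, "z": 0.0})
        b = self._series({"x": -2.0, "y": -2.0, "z": 0.0})
        res = d.overlap_sets(a, b)
        assert res.intersection == {"x", "y"}
        assert res.jaccard == 1.0

    def test_thresholds_are_strict(self):
        a = self._series({"x": 1.0})
        b = self._series({"x": -1.0})
        res = d.overlap_sets(a, b, 1.0, -1.0)
        assert res.set_up == set() and res.set_down == set()

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError):
            d.overlap_sets(self._series({"x": 1.0}), self._series({"y": 1.0}))


def mwu_enumeration_oracle(x, y):
    """Independent oracle: U by pairwise comparison (ties count 1/2) and
    exact two-sided p by enumerating which pooled positions are sample 1."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)

    def u_of(group1):
        rest = [pooled[i] for i in range(n) if i not in group1]
        vals = [pooled[i] for i in group1]
        u = 0.0
        for a in vals:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    observed = u_of(tuple(range(n1)))
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    p_le = sum(u <= observed + 1e-9 for u in us) / len(us)
    p_ge = sum(u >= observed - 1e-9 for u in us) / len(us)
    return observed, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitneyU:
    def test_textbook_example(self):
        # all x below all y: U=0; 2 of 6 arrangements are as extreme
        res = d.mann_whitney_u([1, 2], [3, 4])
        assert res.U == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        res = d.mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_identical_degenerate(self):
        res = d.mann_whitney_u([3, 3, 3], [3, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_symmetry(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        fwd = d.mann_whitney_u(x, y)
        rev = d.mann_whitney_u(y, x)
        assert fwd.U + rev.U == pytest.approx(len(x) * len(y))
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_exact_matches_enumeration_oracle_including_ties(self, rng):
        cases = []
        for n1 in (1, 2, 3, 4, 5, 6):
            for n2 in (1, 3, 6):
                if n1 + n2 > 12:
                    continue
                cases.append(
                    (rng.integers(0, 5, n1).tolist(), rng.integers(0, 5, n2).tolist())
                )
        cases.append(([1.5, 1.5, 2.0], [1.5, 3.0]))  # explicit tied floats
        for x, y in cases:
            res = d.mann_whitney_u(x, y)
            u_oracle, p_oracle = mwu_enumeration_oracle(x, y)
            assert res.U == pytest.approx(u_oracle), (x, y)
            assert res.p_value == pytest.approx(p_oracle), (x, y)

    def test_exact_matches_scipy_untied(self, rng):
        """Independent library oracle on untied data."""
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            res = d.mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert res.U == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact(self, rng):
        """n1=n2=10 untied: approximate p within 0.01 of the exact p."""
        worst = 0.0
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            approx = d.mann_whitney_u(x, y).p_value  # auto -> normal (n=20)
            exact = sps.mannwhitneyu(
                x, y, method="exact", alternative="two-sided"
            ).pvalue
            worst = max(worst, abs(approx - exact))
        assert worst < 0.01

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            d.mann_whitney_u([], [1.0])


class TestChetCompare:
    def _profiles(self, values_a, values_b, bin_width=100):
        n = len(values_a)
        ids = np.array([f"f{i}" for i in range(n)])
        features = pd.DataFrame(
            {
                "chrom": ["c"] * n,
                "start": np.arange(n) * bin_width,
                "end": (np.arange(n) + 1) * bin_width,
            }
        )
        pa = d.OccupancyProfile(ids, np.asarray(values_a, float), 1.0, 0)
        pb = d.OccupancyProfile(ids, np.asarray(values_b, float), 1.0, 0)
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [n * bin_width]})
        return pa, pb, features, regions

    def test_identical_profiles_p_one(self, rng):
        vals = rng.normal(size=50)
        pa, pb, features, regions = self._profiles(vals, vals)
        res = d.chet_compare(pa, pb, features, regions, bin_width=100)
        assert res.mwu.p_value == pytest.approx(1.0)

    def test_downward_shift_detected(self, rng):
        vals = rng.normal(0, 0.5, 300)
        pa, pb, features, regions = self._profiles(vals, vals - 0.5)
        res = d.chet_compare(pa, pb, features, regions, bin_width=100)
        assert res.mwu.p_value < 0.05
        assert res.box_b.median < res.box_a.median

    def test_values_restricted_to_regions(self, rng):
        vals = rng.normal(size=50)
        pa, pb, features, regions = self._profiles(vals, vals)
        regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]})
        res = d.chet_compare(pa, pb, features, regions, bin_width=100)
        assert len(res.bins) == 10
        assert (res.bins["bin_end"] <= 1000).all()

    def test_no_defined_bins_errors(self):
        pa, pb, features, regions = self._profiles([np.nan] * 5, [np.nan] * 5)
        with pytest.raises(ValueError, match="no defined bins"):
            d.chet_compare(pa, pb, features, regions, bin_width=100)

    def test_empty_regions_error(self, rng):
        vals = rng.normal(size=10)
        pa, pb, features, _ = self._profiles(vals, vals)
        with pytest.raises(ValueError, match="cHet"):
            d.chet_compare(pa, pb, features, pd.DataFrame(columns=["chrom", "start", "end"]))


class TestBoxStats:
    def test_quartiles_and_whiskers(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        box = BoxStats.from_values(values)
        assert box.median == 3.0
        assert box.whisker_high == 4.0  # 100 is beyond 1.5 IQR
        assert box.whisker_low == 1.0


class TestQpcr:
    def test_all_equal_cts_fold_change_one_flagged(self):
        res = d.qpcr_foldchange([20, 20], [15, 15], [20, 20], [15, 15])
        np.testing.assert_allclose(res.fold_changes, 1.0)
        assert not res.tested  # zero variance

    def test_ddct_minus_one_gives_twofold(self):
        res = d.qpcr_foldchange([19, 19, 19], [15, 15, 15], [20, 20, 20], [15, 15, 15])
        np.testing.assert_allclose(res.fold_changes, 2.0)

    def test_t_statistic_matches_formula_oracle(self):
        log2_fcs = np.array([0.8, 1.0, 1.2])
        # encode these as ΔΔCt = −log2fc with control ΔCt 0
        res = d.qpcr_foldchange(
            -log2_fcs, [0, 0, 0], [0, 0, 0], [0, 0, 0]
        )
        t_expected = log2_fcs.mean() / (log2_fcs.std(ddof=1) / math.sqrt(3))
        p_expected = 2 * sps.t.sf(abs(t_expected), df=2)
        assert res.t == pytest.approx(t_expected, abs=1e-10)
        assert res.p_value == pytest.approx(p_expected, abs=1e-10)
        assert res.mean_fold_change == pytest.approx((2.0 ** log2_fcs).mean())

    def test_single_replicate_not_tested(self):
        res = d.qpcr_foldchange([19], [15], [20], [15])
        assert not res.tested and res.n_replicates == 1
        np.testing.assert_allclose(res.fold_changes, 2.0)
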