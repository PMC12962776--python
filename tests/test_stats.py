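"""Group-level statistics: permutation trend, coverage, condition agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from ordtune.stats import condition_agreement, coverage_by_rank, width_trend_test
from ordtune.synth import null_region_table


def _table(pref, fwhm, groups=None, region="parietal"):
    n = len(pref)
    return pd.DataFrame({
        "participant_id": ["p1"] * n,
        "region": [region] * n,
        "cluster_id": ["c0"] * n,
        "site_id": [f"s{i}" for i in range(n)],
        "upsampling_group": groups if groups is not None else [f"g{i}" for i in range(n)],
        "preferred_ordinality": pref,
        "fwhm": fwhm,
    })


class TestWidthTrend:
    def test_perfect_monotone_trend(self):
        pref = np.linspace(1, 7, 100)
        tab = _table(pref, fwhm=0.5 + pref)
        res = width_trend_test(tab, "parietal", n_perm=10_000, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_one_tailed <= 0.001

    def test_p_floor_is_one_over_nperm_plus_one(self):
        pref = np.linspace(1, 7, 50)
        tab = _table(pref, fwhm=pref)
        res = width_trend_test(tab, "parietal", n_perm=99, seed=0)
        assert res.p_one_tailed >= 1.0 / 100.0

    def test_null_pvalues_uniform(self):
        """Group-permutation p-values calibrate under a true null."""
        ps = [
            width_trend_test(
                null_region_table(n_groups=50, upsampling=2, seed=rep),
                "parietal", n_perm=199, seed=rep,
            ).p_one_tailed
            for rep in range(150)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / len(ps)
        )

    def test_null_calibrated_with_unequal_group_sizes(self, rng):
        """Size-stratified block permutation stays calibrated when
        exclusion leaves upsampling groups of different sizes."""
        ps = []
        for rep in range(150):
            tab = null_region_table(n_groups=50, upsampling=3, seed=3000 + rep)
            # randomly drop ~a third of sites, unbalancing the groups
            keep = rng.random(len(tab)) > 0.33
            sub = tab[keep]
            ps.append(width_trend_test(sub, "parietal", n_perm=199,
                                       seed=rep).p_one_tailed)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_site_level_permutation_inflates_under_upsampling(self):
        """Replicated sites break site-level exchangeability; group-level
        permutation stays calibrated where site-level rejects far too often."""
        import warnings

        p_grp, p_site = [], []
        for rep in range(100):
            tab = null_region_table(n_groups=30, upsampling=5, jitter=0.01,
                                    seed=500 + rep)
            p_grp.append(width_trend_test(tab, "parietal", n_perm=199,
                                          seed=rep).p_one_tailed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_site.append(width_trend_test(
                    tab.drop(columns=["upsampling_group"]), "parietal",
                    n_perm=199, seed=rep).p_one_tailed)
        assert np.mean(np.asarray(p_grp) <= 0.05) <= 0.12
        assert np.mean(np.asarray(p_site) <= 0.05) > 0.15

    def test_missing_groups_fall_back_with_warning(self):
        tab = _table(np.linspace(1, 7, 30), np.linspace(1, 3, 30))
        tab = tab.drop(columns=["upsampling_group"])
        with pytest.warns(UserWarning, match="site-level"):
            res = width_trend_test(tab, "parietal", n_perm=99, seed=0)
        assert res.permutation_level == "site"

    def test_empty_region_raises(self):
        tab = _table(np.linspace(1, 7, 10), np.ones(10))
        with pytest.raises(ValueError, match="premotor"):
            width_trend_test(tab, "premotor", n_perm=99)


class TestCoverage:
    def test_all_sites_on_first_rank(self):
        tab = _table(np.ones(20), np.ones(20))
        np.testing.assert_allclose(
            coverage_by_rank(tab, "p1", "parietal"),
            [1, 0, 0, 0, 0, 0, 0],
        )

    def test_uniform_preferences_near_one_seventh(self, rng):
        pref = rng.uniform(1, 7.999, 700).clip(1, 7)
        tab = _table(np.floor(pref), np.ones(700))
        frac = coverage_by_rank(tab, "p1", "parietal")
        assert frac.sum() == pytest.approx(1.0)
        assert np.all(np.abs(frac - 1 / 7) < 4 * np.sqrt((1 / 7) * (6 / 7) / 700))

    def test_half_open_binning_convention(self):
        tab = _table([3.5, 7.0], [1.0, 1.0])
        frac = coverage_by_rank(tab, "p1", "parietal")
        assert frac[2] == pytest.approx(0.5)  # 3.5 -> bin 3
        assert frac[6] == pytest.approx(0.5)  # 7.0 -> closed top bin

    @given(k=st.integers(2, 5))
    @settings(deadline=None, max_examples=4, derandomize=True)
    def test_invariant_to_site_duplication(self, k):
        pref = np.array([1.2, 2.7, 4.4, 6.9])
        tab = _table(pref, np.ones(4))
        dup = pd.concat([tab] * k, ignore_index=True)
        dup["site_id"] = [f"s{i}" for i in range(len(dup))]
        np.testing.assert_allclose(
            coverage_by_rank(tab, "p1", "parietal"),
            coverage_by_rank(dup, "p1", "parietal"),
        )


def _fits_frame(pref, clusters):
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(len(pref))],
        "cluster_id": clusters,
        "preferred_ordinality": pref,
    })


class TestConditionAgreement:
    def test_identical_fits_fully_correlated(self, rng):
        pref = rng.uniform(1, 7, 30)
        clusters = np.repeat([f"c{i}" for i in range(3)], 10)
        res = condition_agreement(_fits_frame(pref, clusters),
                                  _fits_frame(pref, clusters))
        assert np.allclose(res["r"], 1.0)
        assert res["significant"].all()

    def test_fdr_flags_match_hand_computed_bh(self, rng):
        """Significance flags equal a step-up BH oracle computed by hand:
        reject the largest k with p_(k) <= k*q/m (e.g. (.01,.02,.04,.5)
        at q=.05 rejects the first three)."""
        # four clusters with decreasing cross-condition agreement
        pref_a, pref_b, clusters = [], [], []
        for i, noise in enumerate([0.3, 0.8, 1.2, 6.0]):
            x = rng.uniform(1, 7, 10)
            pref_a.extend(x)
            pref_b.extend(x + rng.normal(0, noise, 10))
            clusters.extend([f"c{i}"] * 10)
        res = condition_agreement(
            _fits_frame(np.array(pref_a), clusters),
            _fits_frame(np.array(pref_b), clusters),
        )
        p = res["p"].to_numpy()
        m = p.size
        order = np.argsort(p)
        passed = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * 0.05 / m))
        expected = np.zeros(m, dtype=bool)
        if passed.size:
            expected[order[: passed[-1] + 1]] = True
        assert list(res["significant"]) == list(expected)
        assert expected.any() and not expected.all()

    def test_independent_preferences_rarely_significant(self, rng):
        hits = []
        for rep in range(200):
            pref_a = rng.uniform(1, 7, 120)
            pref_b = rng.uniform(1, 7, 120)
            clusters = np.repeat([f"c{i}" for i in range(12)], 10)
            res = condition_agreement(_fits_frame(pref_a, clusters),
                                      _fits_frame(pref_b, clusters))
            hits.append(res["significant"].mean())
        assert np.mean(hits) <= 0.05

    def test_small_cluster_skipped_with_warning(self, rng):
        pref = rng.uniform(1, 7, 12)
        clusters = ["big"] * 10 + ["tiny"] * 2
        with pytest.warns(UserWarning, match="tiny"):
            res = condition_agreement(_fits_frame(pref, clusters),
                                      _fits_frame(pref, clusters))
        assert set(res["cluster_id"]) == {"big"}
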