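"""Log-Gaussian tuning, HRF, forward model, grid fitting, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ordtune.prf import (
    HRFParams,
    LogGaussianTuning,
    PRFGrid,
    SiteTimeSeries,
    cross_validate,
    cross_validate_pairs,
    estimate_hrf_and_refit,
    fit_prf_grid,
    predict_bold,
    two_gamma_hrf,
)
from ordtune.synth import SimSiteSpec, simulate_site


class TestTuning:
    def test_peak_amplitude_is_one_at_mu(self):
        assert LogGaussianTuning(3, 0.5).response(3) == pytest.approx(1.0)

    def test_log_domain_symmetry(self):
        """Equal responses at mu*f and mu/f for any factor f."""
        t = LogGaussianTuning(3, 0.5)
        assert t.response(6) == pytest.approx(t.response(1.5))

    @given(
        mu=st.floats(0.5, 20), sigma=st.floats(0.1, 2), f=st.floats(1.01, 5)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry_property(self, mu, sigma, f):
        t = LogGaussianTuning(mu, sigma)
        assert t.response(mu * f) == pytest.approx(t.response(mu / f), rel=1e-9)

    def test_fwhm_matches_half_maximum_roots(self):
        """Closed-form FWHM equals the numerically solved half-max width."""
        t = LogGaussianTuning(2.0, 0.4)
        half = lambda x: t.response(x) - 0.5
        left = brentq(half, 1e-6, t.mu)
        right = brentq(half, t.mu, 1e3)
        assert t.fwhm == pytest.approx(right - left, rel=1e-9)

    def test_nonpositive_rank_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LogGaussianTuning(3, 0.5).response(0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LogGaussianTuning(-1, 0.5)
        with pytest.raises(ValueError):
            LogGaussianTuning(3, 0.0)


class TestHRF:
    def test_canonical_peak_near_five_seconds(self, canonical_hrf):
        k = two_gamma_hrf(canonical_hrf, sample_rate_hz=100.0)
        assert np.argmax(k) / 100.0 == pytest.approx(5.0, abs=0.05)

    def test_zero_undershoot_is_single_nonnegative_gamma(self):
        k = two_gamma_hrf(HRFParams(undershoot_ratio=0.0), 10.0)
        assert np.all(k >= 0)
        assert k.max() == pytest.approx(1.0)

    def test_peak_time_stable_under_resampling(self, canonical_hrf):
        k1 = two_gamma_hrf(canonical_hrf, 2.0)
        k2 = two_gamma_hrf(canonical_hrf, 4.0)
        assert abs(np.argmax(k1) / 2.0 - np.argmax(k2) / 4.0) <= 0.5

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            HRFParams(peak_dispersion=0.0)

    def test_undershoot_must_follow_peak(self):
        with pytest.raises(ValueError):
            HRFParams(peak_delay=10.0, undershoot_delay=9.0)


class TestPredictBold:
    def test_zero_gain_gives_constant_offset(self, default_design, canonical_hrf):
        p = predict_bold(default_design, LogGaussianTuning(3, 0.5),
                         canonical_hrf, gain=0.0, offset=2.5)
        assert p.shape == (default_design.n_post_discard,)
        assert np.allclose(p, 2.5)

    def test_constant_preferred_rank_settles_at_offset_plus_gain(
        self, canonical_hrf
    ):
        from ordtune import build_run_design

        d = build_run_design(
            volumes_per_rank=40, baseline_seconds=0.0, cycle_count=1,
            n_discard=0, rank_min=3, rank_max=3,
        )
        p = predict_bold(d, LogGaussianTuning(3, 0.5), canonical_hrf,
                         gain=1.2, offset=0.3)
        # unit-area kernel: steady state of a constant unit input is 1
        assert p[-1] == pytest.approx(0.3 + 1.2, rel=1e-3)

    def test_impulse_reproduces_scaled_kernel(self, canonical_hrf):
        """A one-volume presentation convolves to the HRF kernel shape."""
        from ordtune.design import RunDesign
        from ordtune.prf import _tr_kernel

        seq = (3,) + (15,) * 39
        d = RunDesign(tr_seconds=1.5, n_volumes=40, presented_ordinality=seq,
                      n_discard=0, cycle_count=1)
        t = LogGaussianTuning(3.0, 0.1)  # near-delta: baseline response ~ 0
        p = predict_bold(d, t, canonical_hrf)
        k = _tr_kernel(d, canonical_hrf)
        kp = np.r_[k, np.zeros(40 - k.size)]  # zero-padded to run length
        expected = t.response(3.0) * kp + t.response(15.0) * np.convolve(
            np.r_[0.0, np.ones(39)], k
        )[:40]
        assert np.allclose(p, expected, atol=1e-9)

    def test_length_mismatch_raises(self, default_design):
        s = SiteTimeSeries("x", np.zeros(10))
        with pytest.raises(ValueError, match="length"):
            fit_prf_grid(s, default_design)


class TestGridFit:
    def test_noiseless_grid_point_recovered_exactly(self, default_design):
        g = PRFGrid.default()
        mu, sig = float(g.mus[37]), float(g.sigmas[18])
        s, _ = simulate_site(
            SimSiteSpec(mu=mu, sigma=sig, noise_sd=0.0, gain=1.7, offset=0.4),
            default_design,
        )
        f = fit_prf_grid(s, default_design, grid=g)
        assert (f.mu, f.sigma) == (mu, sig)
        assert f.r2_within == pytest.approx(1.0)
        assert f.gain == pytest.approx(1.7, rel=1e-6)
        assert f.offset == pytest.approx(0.4, abs=1e-6)

    def test_out_of_range_preference_recovered_but_excluded(
        self, default_design
    ):
        """A baseline-preferring site is representable yet not included."""
        s, _ = simulate_site(
            SimSiteSpec(mu=15.0, sigma=0.3, noise_sd=0.05, seed=4),
            default_design,
        )
        f = fit_prf_grid(s, default_design)
        assert f.mu > 7.0
        assert not f.included

    def test_zero_variance_series_degenerate(self, default_design):
        f = fit_prf_grid(SiteTimeSeries("flat", np.ones(176)), default_design)
        assert f.r2_within == 0.0
        assert not f.included
        assert f.flag == "degenerate"

    def test_matches_brute_force_search(self, default_design, canonical_hrf):
        """Vectorized search equals a per-candidate brute-force oracle."""
        grid = PRFGrid(mus=np.geomspace(0.9, 40.0, 16),
                       sigmas=np.geomspace(0.05, 3.0, 8))
        preds = {
            (mu, sg): predict_bold(default_design,
                                   LogGaussianTuning(mu, sg), canonical_hrf)
            for mu, sg in grid.candidates()
        }
        rng = np.random.default_rng(5)
        for i in range(10):
            s, _ = simulate_site(
                SimSiteSpec(mu=rng.uniform(1, 7), sigma=rng.uniform(0.1, 1),
                            snr=1.0, seed=int(rng.integers(2**31))),
                default_design,
            )
            best, best_r = None, -np.inf
            for (mu, sg), p in preds.items():
                if np.std(p) < 1e-12:
                    continue
                r = np.corrcoef(p, s.samples)[0, 1]
                if r > best_r and r > 0:
                    best, best_r = (mu, sg), r
            f = fit_prf_grid(s, default_design, grid=grid)
            assert (f.mu, f.sigma) == pytest.approx(best)
            assert f.r2_within == pytest.approx(best_r**2)

    def test_refinement_never_worse_than_grid(self, default_design):
        s, _ = simulate_site(
            SimSiteSpec(mu=3.3, sigma=0.45, snr=2.0, seed=9), default_design
        )
        coarse = fit_prf_grid(s, default_design)
        refined = fit_prf_grid(s, default_design, refine=True)
        assert refined.r2_within >= coarse.r2_within


class TestCrossValidation:
    def test_identity_heldout_equals_within(self, default_design):
        s, _ = simulate_site(
            SimSiteSpec(mu=4.0, sigma=0.5, snr=2.0, seed=1), default_design
        )
        f = fit_prf_grid(s, default_design)
        assert cross_validate(f, s, default_design) == pytest.approx(
            f.r2_within, rel=1e-9
        )

    def test_crossval_not_above_within_on_average(self, default_design):
        rng = np.random.default_rng(6)
        within, cross = [], []
        for _ in range(200):
            mu, sg = rng.uniform(1.5, 6.5), rng.uniform(0.2, 0.9)
            sa, _ = simulate_site(
                SimSiteSpec(mu=mu, sigma=sg, snr=1.0,
                            seed=int(rng.integers(2**31))), default_design)
            sb, _ = simulate_site(
                SimSiteSpec(mu=mu, sigma=sg, snr=1.0,
                            seed=int(rng.integers(2**31))), default_design)
            f = fit_prf_grid(sa, default_design)
            within.append(f.r2_within)
            cross.append(cross_validate(f, sb, default_design))
        assert np.mean(cross) < np.mean(within)

    def test_untuned_noise_site_excluded(self, default_design):
        """A site that is pure noise in both conditions fails the averaged
        cross-validation threshold and is excluded."""
        rng = np.random.default_rng(8)
        excluded = 0
        n = 200
        for _ in range(n):
            sa = SiteTimeSeries("x", rng.standard_normal(176))
            sb = SiteTimeSeries("x", rng.standard_normal(176))
            fa = fit_prf_grid(sa, default_design)
            fb = fit_prf_grid(sb, default_design)
            fa2, _ = cross_validate_pairs(
                [fa], [sa], [fb], [sb], default_design, default_design
            )
            excluded += not fa2[0].included
        assert excluded / n >= 0.95

    def test_design_mismatch_raises(self, default_design):
        from ordtune import build_run_design

        short = build_run_design(cycle_count=2)
        s, _ = simulate_site(SimSiteSpec(mu=3, sigma=0.5, snr=2.0),
                             default_design)
        f = fit_prf_grid(s, default_design)
        with pytest.raises(ValueError, match="length"):
            cross_validate(f, s, short)


class TestHRFEstimation:
    def _population(self, design, hrf, n, seed):
        rng = np.random.default_rng(seed)
        series, fits = [], []
        for i in range(n):
            s, _ = simulate_site(
                SimSiteSpec(mu=rng.uniform(1.5, 6.5),
                            sigma=rng.uniform(0.2, 0.8), snr=6.0, hrf=hrf,
                            seed=int(rng.integers(2**31))),
                design, site_id=f"s{i}")
            series.append(s)
            fits.append(fit_prf_grid(s, design))
        return series, fits

    def test_canonical_data_is_near_fixed_point(self, default_design,
                                                canonical_hrf):
        series, fits = self._population(default_design, canonical_hrf, 15, 1)
        res = estimate_hrf_and_refit(series, default_design, fits)
        assert abs(res.hrf.peak_delay - canonical_hrf.peak_delay) < 1.0
        r2_before = np.mean([f.r2_within for f in fits])
        r2_after = np.mean([f.r2_within for f in res.fits])
        assert r2_after >= r2_before - 0.02

    def test_delayed_peak_recovered_and_fit_improves(self, default_design):
        true_hrf = HRFParams(peak_delay=7.5)
        series, fits = self._population(default_design, true_hrf, 20, 2)
        res = estimate_hrf_and_refit(series, default_design, fits)
        assert res.converged
        assert res.hrf.peak_delay > 6.5  # moved toward the true 7.5 s
        assert np.mean([f.r2_within for f in res.fits]) > np.mean(
            [f.r2_within for f in fits]
        )

    def test_no_qualifying_sites_returns_initial_with_warning(
        self, default_design, canonical_hrf, rng
    ):
        noise = [SiteTimeSeries(f"n{i}", rng.standard_normal(176))
                 for i in range(5)]
        fits = [fit_prf_grid(s, default_design) for s in noise]
        with pytest.warns(UserWarning, match="quality floor"):
            res = estimate_hrf_and_refit(noise, default_design, fits,
                                         quality_floor=0.9)
        assert res.hrf == canonical_hrf
        assert not res.converged
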