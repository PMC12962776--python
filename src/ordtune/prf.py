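"""Ordinality population receptive field (pRF) model.

The pRF of a recording site is summarized by a Gaussian tuning function
over the natural logarithm of ordinal rank, with preferred ordinality mu
(the peak, in rank units) and tuning width sigma (the log-domain standard
deviation, dimensionless).  Tuning width is reported in linear rank units
as the full width at half maximum,

    FWHM = mu * (exp(sigma*sqrt(2 ln 2)) - exp(-sigma*sqrt(2 ln 2))).

A candidate neuronal time course is the tuning amplitude at each TR's
presented ordinality; convolving it with a two-gamma hemodynamic response
function (HRF) gives the predicted BOLD series.  Fitting is an exhaustive
grid search over (mu, sigma) maximizing the Pearson correlation between
prediction and data, with nonnegative gain and free offset obtained by
ordinary least squares.  The grid's mu range deliberately extends well
beyond the presented ranks so that out-of-range solutions (including a
baseline-position preference) are representable; sites whose best mu falls
outside the presented range are excluded from analysis, as are sites whose
cross-condition validation falls below the variance-explained threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal, stats

from .design import RunDesign

__all__ = [
    "LogGaussianTuning",
    "HRFParams",
    "SiteTimeSeries",
    "PRFGrid",
    "PRFFit",
    "HRFRefitResult",
    "two_gamma_hrf",
    "predict_bold",
    "fit_prf_grid",
    "cross_validate",
    "cross_validate_pairs",
    "estimate_hrf_and_refit",
    "CROSSVAL_THRESHOLD",
]

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))

#: Minimum averaged cross-validated variance explained for inclusion.
CROSSVAL_THRESHOLD = 0.20


@dataclass(frozen=True)
class LogGaussianTuning:
    """Gaussian tuning over log rank: preferred ordinality and log-width."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.mu > 0 and np.isfinite(self.mu)):
            raise ValueError(f"preferred ordinality must be positive, got {self.mu}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"tuning width must be positive, got {self.sigma}")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum in linear rank units."""
        s = self.sigma * _SQRT_2LN2
        return self.mu * (np.exp(s) - np.exp(-s))

    def response(self, rank) -> np.ndarray:
        """Tuning amplitude in (0, 1] at one or more positive ranks."""
        rank = np.asarray(rank, dtype=float)
        if np.any(rank <= 0):
            raise ValueError("rank must be positive (log-rank tuning)")
        return np.exp(-((np.log(rank) - np.log(self.mu)) ** 2) / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF parameters (SPM-style canonical defaults, seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self):
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be nonnegative")
        if self.undershoot_delay <= self.peak_delay:
            raise ValueError("undershoot must peak after the response peak")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.peak_delay, self.undershoot_delay, self.peak_dispersion,
             self.undershoot_dispersion, self.undershoot_ratio]
        )

    @classmethod
    def from_array(cls, a) -> "HRFParams":
        return cls(*(float(x) for x in a))


def two_gamma_hrf(
    params: HRFParams, sample_rate_hz: float, duration_s: float = 32.0
) -> np.ndarray:
    """Evaluate the two-gamma impulse response, peak-normalized to 1.

    The kernel is sampled at ``sample_rate_hz`` starting at t = 0 and must
    cover the undershoot tail (use >= 24 s).
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    a1 = params.peak_delay / params.peak_dispersion
    a2 = params.undershoot_delay / params.undershoot_dispersion
    h = stats.gamma.pdf(t, a1, scale=params.peak_dispersion)
    h = h - params.undershoot_ratio * stats.gamma.pdf(
        t, a2, scale=params.undershoot_dispersion
    )
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: nonpositive peak")
    return h / peak


def _tr_kernel(design: RunDesign, hrf: HRFParams, duration_s: float = 32.0):
    """HRF sampled at the TR, normalized to unit area for convolution."""
    k = two_gamma_hrf(hrf, 1.0 / design.tr_seconds, duration_s)
    s = k.sum()
    if abs(s) < 1e-12:
        raise ValueError("HRF kernel integrates to ~0; cannot area-normalize")
    return k / s


def predict_bold(
    design: RunDesign,
    tuning: LogGaussianTuning,
    hrf: HRFParams,
    gain: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Predicted BOLD series for one site, post-discard length.

    The neuronal time course (tuning amplitude at each volume's presented
    ordinality) is formed over the full run including discarded frames,
    convolved causally with the unit-area TR-sampled HRF, and the initial
    discarded frames are then dropped, so hemodynamic carry-over into the
    analyzed window is modeled.
    """
    neural = tuning.response(design.ranks)
    kernel = _tr_kernel(design, hrf)
    conv = np.convolve(neural, kernel)[: design.n_volumes]
    return offset + gain * conv[design.n_discard :]


@dataclass(frozen=True)
class SiteTimeSeries:
    """Measured series at one recording site (post-discard samples)."""

    site_id: str
    samples: np.ndarray
    condition_label: str = "other"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"site {self.site_id}: non-finite samples")


@dataclass(frozen=True)
class PRFGrid:
    """Candidate (mu, sigma) set for the exhaustive search.

    The default mu range [0.9, 40] strictly contains the presented ranks
    1..7 and the baseline position 15, so both out-of-range and
    baseline-preferring solutions are representable.
    """

    mus: np.ndarray
    sigmas: np.ndarray

    @classmethod
    def default(cls, n_mu: int = 80, n_sigma: int = 40) -> "PRFGrid":
        return cls(
            mus=np.geomspace(0.9, 40.0, n_mu),
            sigmas=np.geomspace(0.05, 3.0, n_sigma),
        )

    def candidates(self):
        """(mu, sigma) pairs ordered by sigma then mu (the tie-break order)."""
        for s in self.sigmas:
            for m in self.mus:
                yield float(m), float(s)


@dataclass
class PRFFit:
    """Per-site grid-search outcome."""

    site_id: str
    tuning: LogGaussianTuning
    gain: float
    offset: float
    r2_within: float
    r2_crossval: float | None = None
    included: bool = False
    flag: str = ""

    @property
    def mu(self):
        return self.tuning.mu

    @property
    def sigma(self):
        return self.tuning.sigma

    @property
    def fwhm(self):
        return self.tuning.fwhm

    def in_presented_range(self, lo: float = 1.0, hi: float = 7.0) -> bool:
        return lo <= self.tuning.mu <= hi


def _prediction_matrix(design: RunDesign, grid: PRFGrid, hrf: HRFParams) -> np.ndarray:
    """Unit-gain predictions for every candidate; shape (n_cand, n_post).

    Row order matches ``grid.candidates()`` (sigma-major), so the first
    maximum along rows realizes the smaller-sigma-then-smaller-mu tie-break.
    """
    ranks = design.ranks
    uniq, inv = np.unique(ranks, return_inverse=True)
    log_u = np.log(uniq)
    log_m = np.log(grid.mus)
    # responses: (n_sigma, n_mu, n_uniq) -> flatten candidate axes sigma-major
    d = log_u[None, None, :] - log_m[None, :, None]
    resp = np.exp(-(d**2) / (2.0 * grid.sigmas[:, None, None] ** 2))
    resp = resp.reshape(-1, uniq.size)
    neural = resp[:, inv]
    kernel = _tr_kernel(design, hrf)
    conv = signal.fftconvolve(neural, kernel[None, :], axes=1)[:, : design.n_volumes]
    return conv[:, design.n_discard :]


class _PredictionCache(dict):
    """Per-(design, grid, hrf) precomputations shared across site fits."""

    def get(self, design, grid, hrf):
        key = (
            design.tr_seconds, design.presented_ordinality, design.n_discard,
            grid.mus.tobytes(), grid.sigmas.tobytes(), hrf,
        )
        if key not in self:
            P = _prediction_matrix(design, grid, hrf)
            P0 = P - P.mean(axis=1, keepdims=True)
            sp = np.sqrt((P0**2).sum(axis=1))
            cand = np.array(list(grid.candidates()))
            if len(self) > 32:  # bound memory across many HRF candidates
                self.clear()
            self[key] = (P, P0, sp, cand)
        return self[key]


_cache = _PredictionCache()


def fit_prf_grid(
    series: SiteTimeSeries,
    design: RunDesign,
    hrf: HRFParams | None = None,
    grid: PRFGrid | None = None,
    refine: bool = False,
) -> PRFFit:
    """Exhaustive (mu, sigma) search for one site.

    Returns the candidate whose prediction is best Pearson-correlated with
    the data, subject to a nonnegative fitted gain; ties break toward
    smaller sigma then smaller mu.  ``r2_within`` is the squared
    correlation of the winner.  A zero-variance series yields a degenerate
    fit (r2 = 0, excluded).
    """
    hrf = hrf or HRFParams()
    grid = grid or PRFGrid.default()
    d = series.samples
    if d.size != design.n_post_discard:
        raise ValueError(
            f"series length {d.size} != post-discard design length "
            f"{design.n_post_discard}"
        )
    P, P0, sp, cand = _cache.get(design, grid, hrf)
    d0 = d - d.mean()
    sd = np.sqrt((d0**2).sum())
    if sd == 0.0:
        return PRFFit(series.site_id, LogGaussianTuning(*cand[0]), 0.0,
                      float(d.mean()), 0.0, flag="degenerate")
    ok = sp > 1e-12
    r = np.full(P.shape[0], -np.inf)
    r[ok] = (P0[ok] @ d0) / (sp[ok] * sd)
    # nonnegative-gain constraint: a candidate with r < 0 would need g < 0
    r[r < 0] = -np.inf
    if not np.isfinite(r).any():
        return PRFFit(series.site_id, LogGaussianTuning(*cand[0]), 0.0,
                      float(d.mean()), 0.0, flag="degenerate")
    i = int(np.argmax(r))  # first max in sigma-major order = tie-break
    mu, sig = cand[i]
    p0 = P0[i]
    gain = float((p0 @ d0) / (p0 @ p0))
    offset = float(d.mean() - gain * P[i].mean())
    best_r = float(r[i])
    tuning = LogGaussianTuning(mu, sig)
    if refine:
        tuning, best_r, gain, offset = _refine_fit(
            d, design, hrf, tuning, best_r, gain, offset
        )
    fit = PRFFit(series.site_id, tuning, gain, offset, best_r**2)
    fit.included = fit.in_presented_range(design.rank_min, design.rank_max)
    return fit


def _refine_fit(d, design, hrf, tuning, best_r, gain, offset):
    """Local continuous refinement seeded at the grid winner.

    Never decreases the correlation: the refined optimum is accepted only
    if it improves on the grid value.
    """
    d0 = d - d.mean()
    sd = np.sqrt((d0**2).sum())

    def neg_corr(theta):
        t = LogGaussianTuning(np.exp(theta[0]), np.exp(theta[1]))
        p = predict_bold(design, t, hrf)
        p0 = p - p.mean()
        n = np.sqrt((p0**2).sum())
        if n < 1e-12:
            return 1.0
        return -float(p0 @ d0 / (n * sd))

    res = optimize.minimize(
        neg_corr,
        [np.log(tuning.mu), np.log(tuning.sigma)],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200},
    )
    if -res.fun > max(best_r, 0.0):
        # accepted only on strict improvement; r > 0 implies a positive gain
        cand = LogGaussianTuning(float(np.exp(res.x[0])), float(np.exp(res.x[1])))
        p = predict_bold(design, cand, hrf)
        p0 = p - p.mean()
        g = float(p0 @ d0 / (p0 @ p0))
        if g >= 0:
            tuning, best_r, gain = cand, -res.fun, g
            offset = float(d.mean() - gain * p.mean())
    return tuning, best_r, gain, offset


def cross_validate(
    fit: PRFFit,
    other_series: SiteTimeSeries,
    other_design: RunDesign,
    hrf: HRFParams | None = None,
) -> float:
    """Variance explained by the frozen tuning on the held-out condition.

    Computed as the squared Pearson correlation between the frozen-parameter
    prediction and the held-out series, floored at zero when the correlation
    is negative (the model's gain is nonnegative, so an anticorrelated
    prediction explains nothing).
    """
    hrf = hrf or HRFParams()
    if other_series.samples.size != other_design.n_post_discard:
        raise ValueError("held-out series length does not match its design")
    p = predict_bold(other_design, fit.tuning, hrf)
    if np.std(p) < 1e-12 or np.std(other_series.samples) < 1e-12:
        return 0.0
    r = float(np.corrcoef(p, other_series.samples)[0, 1])
    return max(r, 0.0) ** 2


def cross_validate_pairs(
    fits_a: list,
    series_a: list,
    fits_b: list,
    series_b: list,
    design_a: RunDesign,
    design_b: RunDesign,
    hrf: HRFParams | None = None,
    threshold: float = CROSSVAL_THRESHOLD,
) -> tuple:
    """Condition-wise cross-validation for matched site lists.

    For each site, the fit from condition A is evaluated on the condition-B
    series and vice versa; the two variance-explained values are averaged
    before applying the inclusion threshold.  A site is included when its
    preferred ordinality lies in the presented range and the averaged
    cross-validated variance explained reaches ``threshold``.
    """
    out_a, out_b = [], []
    for fa, sa, fb, sb in zip(fits_a, series_a, fits_b, series_b):
        if fa.site_id != fb.site_id:
            raise ValueError("site order mismatch between conditions")
        cv_ab = cross_validate(fa, sb, design_b, hrf)
        cv_ba = cross_validate(fb, sa, design_a, hrf)
        mean_cv = 0.5 * (cv_ab + cv_ba)
        passed = mean_cv >= threshold
        fa = replace_fit(fa, r2_crossval=cv_ab,
                         included=passed and fa.in_presented_range(
                             design_a.rank_min, design_a.rank_max))
        fb = replace_fit(fb, r2_crossval=cv_ba,
                         included=passed and fb.in_presented_range(
                             design_b.rank_min, design_b.rank_max))
        out_a.append(fa)
        out_b.append(fb)
    return out_a, out_b


def replace_fit(fit: PRFFit, **kw) -> PRFFit:
    new = PRFFit(fit.site_id, fit.tuning, fit.gain, fit.offset, fit.r2_within,
                 fit.r2_crossval, fit.included, fit.flag)
    for k, v in kw.items():
        setattr(new, k, v)
    return new


@dataclass
class HRFRefitResult:
    hrf: HRFParams
    fits: list
    converged: bool
    message: str = ""


_HRF_BOUNDS = (
    np.array([3.0, 8.0, 0.2, 0.2, 0.0]),
    np.array([9.0, 24.0, 3.0, 3.0, 1.0]),
)


def estimate_hrf_and_refit(
    series_list: list,
    design: RunDesign,
    fits: list,
    initial_hrf: HRFParams | None = None,
    grid: PRFGrid | None = None,
    quality_floor: float = 0.2,
) -> HRFRefitResult:
    """Subject-level HRF estimation followed by a pRF refit.

    With each site's tuning held fixed at its current estimate, the five
    two-gamma parameters are optimized by bounded nonlinear least squares
    to minimize the pooled residual over the best-fitting sites (top
    quartile of r2_within among those above ``quality_floor``); gain and
    offset are re-solved by OLS inside the objective.  All sites are then
    refit with the estimated HRF.  If no site qualifies or the optimizer
    fails to reduce the pooled residual, the initial HRF is returned
    unchanged with ``converged=False``.
    """
    initial_hrf = initial_hrf or HRFParams()
    grid = grid or PRFGrid.default()
    r2 = np.array([f.r2_within for f in fits])
    qual = r2 >= quality_floor
    if not qual.any():
        warnings.warn("no site above the HRF quality floor; keeping initial HRF")
        return HRFRefitResult(initial_hrf, list(fits), False, "no qualifying sites")
    cut = np.quantile(r2[qual], 0.75)
    sel = [i for i in range(len(fits)) if qual[i] and r2[i] >= cut]
    data = [np.asarray(series_list[i].samples, dtype=float) for i in sel]
    tunings = [fits[i].tuning for i in sel]

    def pooled_residual(theta):
        try:
            hrf = HRFParams.from_array(theta)
        except ValueError:
            return np.full(sum(d.size for d in data), 1e6)
        res = []
        for d, t in zip(data, tunings):
            p = predict_bold(design, t, hrf)
            p0 = p - p.mean()
            den = p0 @ p0
            g = max(float(p0 @ (d - d.mean()) / den), 0.0) if den > 1e-12 else 0.0
            res.append(d - (d.mean() - g * p.mean()) - g * p)
        return np.concatenate(res)

    base_sse = float((pooled_residual(initial_hrf.as_array()) ** 2).sum())
    try:
        sol = optimize.least_squares(
            pooled_residual,
            initial_hrf.as_array(),
            bounds=_HRF_BOUNDS,
            xtol=1e-8,
            max_nfev=60,
        )
        new_sse = float((sol.fun**2).sum())
        ok = sol.success and new_sse <= base_sse
    except Exception:
        ok = False
    if not ok:
        warnings.warn("HRF estimation did not improve the pooled residual")
        return HRFRefitResult(initial_hrf, list(fits), False, "optimizer fallback")
    hrf = HRFParams.from_array(sol.x)
    refits = [
        fit_prf_grid(s, design, hrf, grid) for s in series_list
    ]
    # preserve inclusion semantics: refits carry only the range rule until
    # cross-validation is recomputed by the caller
    return HRFRefitResult(hrf, refits, True)
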