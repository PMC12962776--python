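"""Ground-truth generators for every stage of the pipeline.

No scan data is deposited with the study this package models, so each
analysis stage is validated against simulations with known truth: BOLD
series generated from known log-Gaussian tuning through the same forward
model the fitter assumes, two-condition populations with a configurable
width-versus-rank law and upsampling structure, and planted CNN unit
response tables for the selectivity screen.

All generators are seed-deterministic and return machine-readable truth
records alongside the simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import RunDesign
from .prf import HRFParams, LogGaussianTuning, SiteTimeSeries, predict_bold

__all__ = [
    "SimSiteSpec",
    "SimPopulationSpec",
    "simulate_site",
    "simulate_population",
    "plant_cnn_units",
    "noise_sd_for_snr",
]


@dataclass(frozen=True)
class SimSiteSpec:
    """Truth for one simulated recording site.

    Exactly one of ``noise_sd`` (noise standard deviation in signal units)
    or ``snr`` (signal variance over noise variance) must be given.  The
    AR(1) option models the temporal autocorrelation of BOLD noise; its
    innovations are scaled so the marginal noise variance matches the
    requested level.
    """

    mu: float
    sigma: float
    gain: float = 1.0
    offset: float = 0.0
    noise_model: str = "white"  # or "ar1"
    noise_sd: float | None = None
    snr: float | None = None
    ar_coef: float = 0.4
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self):
        if (self.noise_sd is None) == (self.snr is None):
            raise ValueError("specify exactly one of noise_sd or snr")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if not -1 < self.ar_coef < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def noise_sd_for_snr(signal: np.ndarray, snr: float) -> float:
    """Noise standard deviation giving the requested signal/noise variance ratio."""
    return float(np.sqrt(np.var(signal) / snr))


def _noise(model: str, ar_coef: float, n: int, sd: float,
           rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if model == "white":
        return rng.normal(0.0, sd, n)
    # AR(1) with marginal variance sd^2
    innov_sd = sd * np.sqrt(1 - ar_coef**2)
    e = rng.normal(0.0, innov_sd, n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = ar_coef * out[t - 1] + e[t]
    return out


def simulate_site(
    spec: SimSiteSpec,
    design: RunDesign,
    site_id: str = "sim",
    condition_label: str = "other",
) -> tuple:
    """Simulate one site's series; returns (SiteTimeSeries, truth dict)."""
    tuning = LogGaussianTuning(spec.mu, spec.sigma)
    signal = predict_bold(design, tuning, spec.hrf, spec.gain, spec.offset)
    sd = spec.noise_sd if spec.noise_sd is not None else noise_sd_for_snr(signal, spec.snr)
    rng = np.random.default_rng(spec.seed)
    samples = signal + _noise(spec.noise_model, spec.ar_coef, signal.size, sd, rng)
    truth = {
        "site_id": site_id,
        "mu": spec.mu,
        "sigma": spec.sigma,
        "fwhm": tuning.fwhm,
        "gain": spec.gain,
        "offset": spec.offset,
        "noise_sd": sd,
        "noise_model": spec.noise_model,
        "seed": spec.seed,
    }
    return SiteTimeSeries(site_id, samples, condition_label), truth


@dataclass(frozen=True)
class SimPopulationSpec:
    """A synthetic two-condition population of tuned sites.

    ``mu_distribution`` — "lowskew" draws preferred ordinality with density
    proportional to 1/mu over [1, 7] (mirroring the empirical preference
    for early ranks); "uniform" draws uniformly.

    ``width_law`` controls how tuning width relates to preferred rank:

    * "log_affine" — sigma(mu) = intercept + slope * ln(mu).  A positive
      slope plants a width-increases-with-rank effect.  Note that even at
      slope 0 the *linear* width FWHM = 2 mu sinh(sigma sqrt(2 ln 2))
      grows proportionally with mu (constant log-width is a constant
      Weber fraction), so slope 0 is a null for sigma, not for FWHM.
    * "fwhm_independent" — the FWHM target is drawn uniformly on
      [width_intercept, width_intercept + width_slope] rank units,
      independent of mu, and inverted to sigma.  This is the genuine null
      for the FWHM-versus-rank trend test.

    ``upsampling`` replicates each source site k times with a shared
    noiseless signal and independent noise, emulating interpolation of
    acquired voxels onto a finer anatomical grid.
    """

    n_sites: int = 100
    mu_distribution: str = "lowskew"
    width_law: str = "log_affine"
    width_intercept: float = 0.35
    width_slope: float = 0.15
    snr: float = 1.0
    noise_model: str = "white"
    upsampling: int = 1
    gain: float = 1.0
    offset: float = 0.0
    region: str = "parietal"
    participant_id: str = "sim01"
    seed: int = 0

    def __post_init__(self):
        if self.upsampling < 1:
            raise ValueError("upsampling factor must be >= 1")
        if self.width_law not in ("log_affine", "fwhm_independent"):
            raise ValueError(f"unknown width law {self.width_law!r}")
        if self.width_law == "log_affine" and (
            self.width_intercept + self.width_slope * np.log(7.0) <= 0
            or self.width_intercept <= 0
        ):
            raise ValueError("width law must give sigma > 0 over [1, 7]")
        if self.width_law == "fwhm_independent" and self.width_intercept <= 0:
            raise ValueError("fwhm_independent law needs a positive width floor")
        if self.mu_distribution not in ("lowskew", "uniform"):
            raise ValueError(f"unknown mu distribution {self.mu_distribution!r}")


def _draw_mu(spec: SimPopulationSpec, rng) -> np.ndarray:
    if spec.mu_distribution == "uniform":
        return rng.uniform(1.0, 7.0, spec.n_sites)
    # density ~ 1/mu on [1, 7]  <=>  ln(mu) uniform on [0, ln 7]
    return np.exp(rng.uniform(0.0, np.log(7.0), spec.n_sites))


def simulate_population(
    spec: SimPopulationSpec,
    design_a: RunDesign,
    design_b: RunDesign,
) -> dict:
    """Simulate a two-condition population ready for the full pipeline.

    Returns a dict with per-condition series lists (``series_a``,
    ``series_b``; matched order, replicated ``upsampling`` times per source
    site with independent noise) and a ``truth`` DataFrame carrying
    participant, region, upsampling_group and the generating parameters —
    the columns the region-statistics stage expects.
    """
    rng = np.random.default_rng(spec.seed)
    mus = _draw_mu(spec, rng)
    if spec.width_law == "log_affine":
        sigmas = spec.width_intercept + spec.width_slope * np.log(mus)
    else:  # FWHM drawn independent of mu, inverted to the log-domain width
        fwhms = rng.uniform(spec.width_intercept,
                            spec.width_intercept + spec.width_slope, spec.n_sites)
        sigmas = np.arcsinh(fwhms / (2.0 * mus)) / np.sqrt(2.0 * np.log(2.0))
    series_a, series_b, rows = [], [], []
    for i in range(spec.n_sites):
        tuning = LogGaussianTuning(float(mus[i]), float(sigmas[i]))
        sig_a = predict_bold(design_a, tuning, HRFParams(), spec.gain, spec.offset)
        sig_b = predict_bold(design_b, tuning, HRFParams(), spec.gain, spec.offset)
        sd_a = noise_sd_for_snr(sig_a, spec.snr)
        sd_b = noise_sd_for_snr(sig_b, spec.snr)
        for k in range(spec.upsampling):
            sid = f"s{i:04d}r{k}"
            samp_a = sig_a + _noise(spec.noise_model, 0.4, sig_a.size, sd_a, rng)
            samp_b = sig_b + _noise(spec.noise_model, 0.4, sig_b.size, sd_b, rng)
            series_a.append(SiteTimeSeries(sid, samp_a, "rectangular"))
            series_b.append(SiteTimeSeries(sid, samp_b, "polygon"))
            rows.append({
                "participant_id": spec.participant_id,
                "region": spec.region,
                "cluster_id": "c0",
                "site_id": sid,
                "upsampling_group": f"g{i:04d}",
                "true_mu": float(mus[i]),
                "true_sigma": float(sigmas[i]),
                "true_fwhm": tuning.fwhm,
            })
    return {
        "series_a": series_a,
        "series_b": series_b,
        "truth": pd.DataFrame(rows),
    }


def null_region_table(
    n_groups: int = 100,
    upsampling: int = 1,
    jitter: float = 0.05,
    region: str = "parietal",
    seed: int = 0,
) -> pd.DataFrame:
    """Region table with tuning width independent of preferred rank.

    Each upsampling group draws one (preferred ordinality, fwhm) pair with
    the two quantities independent; its ``upsampling`` member sites carry
    the group values plus small correlated-within-group jitter, emulating
    near-duplicate sites interpolated from one acquired voxel.  Used to
    calibrate the permutation trend test and to demonstrate that site-level
    permutation is anticonservative when sites are upsampled.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        mu = rng.uniform(1.0, 7.0)
        fwhm = rng.uniform(0.5, 6.0)
        for k in range(upsampling):
            rows.append({
                "participant_id": "nullsim",  # a literal "null" trips CSV NA parsing
                "region": region,
                "cluster_id": "c0",
                "site_id": f"s{g:04d}r{k}",
                "upsampling_group": f"g{g:04d}",
                "preferred_ordinality": float(
                    np.clip(mu + rng.normal(0, jitter), 1.0, 7.0)
                ),
                "fwhm": float(max(fwhm + rng.normal(0, jitter), 1e-3)),
            })
    return pd.DataFrame(rows)


def plant_cnn_units(
    labels: pd.DataFrame,
    tunings: list,
    n_null: int = 0,
    noise_sd: float = 0.1,
    set_effect: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
):
    """Plant tuned, null and set-nuisance unit responses for a label table.

    ``tunings`` is a list of (mu, sigma) pairs; each becomes one unit whose
    response to an image is the log-Gaussian amplitude at the image's
    ordinality, times ``gain``, plus white noise.  ``n_null`` appends
    pure-noise units.  A nonzero ``set_effect`` adds a stimulus-set offset
    (+ for the first set label, - for the other) to *every* planted unit,
    for negative-control experiments.

    Returns (responses array of shape (n_units, n_images), truth DataFrame).
    """
    from .cnn.analysis import UnitResponseTable  # local: avoid import cycle

    rng = np.random.default_rng(seed)
    ords = labels["ordinality"].to_numpy(dtype=float)
    sets = labels["stimulus_set"].to_numpy()
    set_sign = np.where(sets == sets[0], 1.0, -1.0)
    n_img = len(labels)
    units = []
    truth = []
    for j, (mu, sig) in enumerate(tunings):
        resp = gain * LogGaussianTuning(mu, sig).response(ords)
        resp = resp + set_effect * set_sign + rng.normal(0.0, noise_sd, n_img)
        units.append(resp)
        truth.append({"unit_id": j, "kind": "tuned", "mu": mu, "sigma": sig})
    for j in range(n_null):
        units.append(rng.normal(0.0, noise_sd if noise_sd > 0 else 1.0, n_img))
        truth.append({"unit_id": len(tunings) + j, "kind": "null",
                      "mu": np.nan, "sigma": np.nan})
    responses = np.asarray(units, dtype=np.float32)
    return UnitResponseTable(responses, labels.reset_index(drop=True),
                             layer="planted"), pd.DataFrame(truth)
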