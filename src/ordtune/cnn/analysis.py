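"""Unit-level ordinality analysis of network activations.

The screening stage runs, for every unit of the analysis layer, a two-way
fixed-effects ANOVA with ordinality and stimulus set as factors (balanced
design, interaction included).  A unit is ordinality-selective when the
ordinality main effect is significant while neither the stimulus-set main
effect nor the interaction is — selectivity must generalize across
stimulus sets.  Because the generator guarantees balance, the ANOVA is
computed directly from sums of squares, vectorized across all units.

Selected units are characterized by their preferred ordinality (argmax of
the per-ordinality mean response), pooled into normalized tuning curves
per preferred rank, summarized by least-squares Gaussian fits whose widths
are tested for an increase with rank (one-tailed Kendall tau), and fed to
a linear SVM decoding "first" versus all other ordinalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "UnitResponseTable",
    "extract_responses",
    "screen_selectivity",
    "pool_tuning_curves",
    "GaussianFit",
    "fit_curve_gaussian",
    "width_rank_tau",
    "SVMResult",
    "svm_first_vs_rest",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class UnitResponseTable:
    """Activations of one layer's units to a labeled image set.

    ``responses`` has shape (n_units, n_images); ``labels`` has one row
    per image and must carry ``ordinality`` and ``stimulus_set`` columns.
    """

    responses: np.ndarray
    labels: pd.DataFrame
    layer: str = ""

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be (n_units, n_images)")
        if self.responses.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.responses.shape[1]} response columns vs "
                f"{len(self.labels)} label rows"
            )

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @property
    def ordinality_levels(self) -> np.ndarray:
        return np.unique(self.labels["ordinality"].to_numpy())

    def cell_counts(self) -> pd.Series:
        return self.labels.groupby(["ordinality", "stimulus_set"]).size()


def extract_responses(model, images, labels, layer=None, batch_size=4):
    """Run images through the network and tabulate per-unit activations."""
    from .stimuli import preprocess_images

    batch = images
    if batch.ndim == 4 and batch.shape[-1] == 3:  # raw uint8 images
        batch = preprocess_images(images)
    acts = model.activations(batch, layer=layer, batch_size=batch_size)
    return UnitResponseTable(acts.T, labels.reset_index(drop=True),
                             layer=layer or model.spec.analysis_layer)


def _balanced_anova(Y, a_idx, b_idx, n_a, n_b):
    """Vectorized balanced two-way ANOVA with interaction.

    Y: (n_units, N); a_idx/b_idx: factor level index per observation.
    Returns (p_a, p_b, p_ab, mean_by_a) with flat units given p = 1.
    """
    U, N = Y.shape
    cell_idx = a_idx * n_b + b_idx
    counts = np.bincount(cell_idx, minlength=n_a * n_b)
    if np.unique(counts).size != 1:
        bad = {divmod(i, n_b): int(c) for i, c in enumerate(counts)}
        raise ValueError(f"unbalanced (ordinality x set) cells: {bad}")
    n_rep = int(counts[0])
    if n_rep < 2:
        raise ValueError("need >= 2 replicates per cell for the interaction term")

    gm = Y.mean(axis=1, keepdims=True)
    onehot_a = np.eye(n_a)[a_idx]  # (N, n_a)
    onehot_b = np.eye(n_b)[b_idx]
    onehot_c = np.eye(n_a * n_b)[cell_idx]
    mean_a = (Y @ onehot_a) / (N / n_a)
    mean_b = (Y @ onehot_b) / (N / n_b)
    mean_c = (Y @ onehot_c) / n_rep

    ss_a = (N / n_a) * ((mean_a - gm) ** 2).sum(axis=1)
    ss_b = (N / n_b) * ((mean_b - gm) ** 2).sum(axis=1)
    cell_pred = (mean_c.reshape(U, n_a, n_b)
                 - mean_a[:, :, None] - mean_b[:, None, :] + gm[:, :, None])
    ss_ab = n_rep * (cell_pred**2).sum(axis=(1, 2))
    ss_tot = ((Y - gm) ** 2).sum(axis=1)
    ss_e = np.maximum(ss_tot - ss_a - ss_b - ss_ab, 0.0)

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_e = n_a * n_b * (n_rep - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = ss_e / df_e
        f_a = (ss_a / df_a) / mse
        f_b = (ss_b / df_b) / mse
        f_ab = (ss_ab / df_ab) / mse
    p_a = sps.f.sf(f_a, df_a, df_e)
    p_b = sps.f.sf(f_b, df_b, df_e)
    p_ab = sps.f.sf(f_ab, df_ab, df_e)

    flat = ss_tot <= 1e-12 * np.maximum(np.abs(gm[:, 0]) ** 2, 1.0)
    for p in (p_a, p_b, p_ab):
        p[flat] = 1.0
        p[np.isnan(p)] = 1.0
    return p_a, p_b, p_ab, mean_a


def screen_selectivity(table: UnitResponseTable, alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA selectivity screen over all units.

    Returns one row per unit: p_ordinality, p_set, p_interaction, the
    compound ``selected`` flag (ordinality effect significant, set and
    interaction effects not), and preferred_ordinality (argmax of the
    per-ordinality mean response).  Zero-variance units are reported
    unselected with p = 1.
    """
    ords = table.labels["ordinality"].to_numpy()
    sets = table.labels["stimulus_set"].to_numpy()
    a_levels, a_idx = np.unique(ords, return_inverse=True)
    b_levels, b_idx = np.unique(sets, return_inverse=True)
    Y = np.asarray(table.responses, dtype=np.float64)
    p_a, p_b, p_ab, mean_a = _balanced_anova(
        Y, a_idx, b_idx, a_levels.size, b_levels.size
    )
    preferred = a_levels[np.argmax(mean_a, axis=1)]
    selected = (p_a < alpha) & (p_b >= alpha) & (p_ab >= alpha)
    return pd.DataFrame({
        "unit_id": np.arange(table.n_units),
        "p_ordinality": p_a,
        "p_set": p_b,
        "p_interaction": p_ab,
        "selected": selected,
        "preferred_ordinality": preferred,
    })


def pool_tuning_curves(
    table: UnitResponseTable,
    selectivity: pd.DataFrame,
    ordinality_levels=None,
) -> pd.DataFrame:
    """Pooled normalized tuning curves of selected units.

    Each selected unit's per-ordinality mean response is min-max scaled to
    [0, 1]; units sharing a preferred ordinality are then averaged.  The
    result has one row per (preferred_ordinality, ordinality) with the
    pooled mean, the standard error over units, and the unit count.
    Empty groups are simply absent.
    """
    ords = table.labels["ordinality"].to_numpy()
    levels = (np.unique(ords) if ordinality_levels is None
              else np.asarray(ordinality_levels))
    sel = selectivity[selectivity["selected"]]
    if sel.empty:
        return pd.DataFrame(
            columns=["preferred_ordinality", "ordinality", "mean_response",
                     "se", "n_units"]
        )
    masks = [ords == lv for lv in levels]
    rows = []
    for pref, grp in sel.groupby("preferred_ordinality"):
        curves = []
        for uid in grp["unit_id"]:
            resp = np.asarray(table.responses[uid], dtype=float)
            curve = np.array([resp[m].mean() for m in masks])
            span = curve.max() - curve.min()
            if span <= 0:
                continue
            curves.append((curve - curve.min()) / span)
        if not curves:
            continue
        curves = np.asarray(curves)
        mean = curves.mean(axis=0)
        se = (curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
              if len(curves) > 1 else np.zeros(levels.size))
        for lv, m, s in zip(levels, mean, se):
            rows.append({"preferred_ordinality": pref, "ordinality": lv,
                         "mean_response": m, "se": s, "n_units": len(curves)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian summary of one tuning curve."""

    center: float
    sigma: float
    fwhm: float
    amplitude: float
    baseline: float
    r2: float
    ok: bool
    flag: str = ""


def fit_curve_gaussian(values, ranks) -> GaussianFit:
    """Fit baseline + amplitude * exp(-(x - c)^2 / (2 s^2)) on linear rank.

    Width is reported as FWHM = 2 sqrt(2 ln 2) * s.  A flat curve or a
    non-converging fit is flagged (``ok=False``) and should be excluded
    from downstream rank-width statistics.
    """
    x = np.asarray(ranks, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 points to fit a four-parameter Gaussian")
    span = y.max() - y.min()
    if span <= 1e-12:
        return GaussianFit(np.nan, np.nan, np.nan, 0.0, float(y.mean()),
                           0.0, False, "flat curve")

    def model(x, base, amp, c, s):
        return base + amp * np.exp(-((x - c) ** 2) / (2.0 * s**2))

    p0 = [float(y.min()), float(span), float(x[np.argmax(y)]), 1.0]
    lo = [-np.inf, 0.0, x.min() - 2 * (x.max() - x.min()), 1e-3]
    hi = [np.inf, np.inf, x.max() + 2 * (x.max() - x.min()), 50.0]
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=(lo, hi),
                                     maxfev=5000)
    except (RuntimeError, ValueError):
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, np.nan, 0.0,
                           False, "no convergence")
    base, amp, c, s = (float(v) for v in popt)
    resid = y - model(x, *popt)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    flag = ""
    if not (x.min() <= c <= x.max()):
        flag = "center outside sampled ranks"
    return GaussianFit(c, s, _FWHM_PER_SIGMA * s, amp, base, float(r2),
                       True, flag)


def width_rank_tau(widths, centers) -> tuple:
    """One-tailed Kendall correlation of tuning width against center.

    Tests for widths increasing with preferred rank; returns (tau,
    one-tailed p).  An input whose ranks are all tied yields p = 1 with a
    warning.
    """
    widths = np.asarray(widths, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if widths.size < 3:
        raise ValueError("need >= 3 (width, center) pairs")
    if np.unique(centers).size == 1 or np.unique(widths).size == 1:
        warnings.warn("all-tied input to the width-rank test; p = 1")
        return 0.0, 1.0
    res = sps.kendalltau(centers, widths, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def unit_analysis_pipeline(
    model,
    seed: int = 0,
    reps_straight: int = 5,
    alpha: float = 0.05,
    batch_size: int = 4,
) -> dict:
    """Stimuli -> network -> screen -> pooled curves -> Gaussian widths -> tau.

    Runs the whole unit-analysis chain on freshly generated screening
    stimuli and whatever weights the model carries.  The chain is
    weight-agnostic: with few or no selected units the later stages return
    empty results and the rank-width statistic is reported as NaN rather
    than failing.
    """
    from .stimuli import build_screening_dataset

    images, labels = build_screening_dataset(seed=seed,
                                             reps_straight=reps_straight)
    table = extract_responses(model, images, labels, batch_size=batch_size)
    selectivity = screen_selectivity(table, alpha=alpha)
    pooled = pool_tuning_curves(table, selectivity)
    centers, widths = [], []
    for pref, grp in pooled.groupby("preferred_ordinality"):
        grp = grp.sort_values("ordinality")
        if len(grp) < 4:
            continue
        fit = fit_curve_gaussian(grp["mean_response"].to_numpy(),
                                 grp["ordinality"].to_numpy(dtype=float))
        if fit.ok:
            centers.append(float(pref))
            widths.append(fit.fwhm)
    if len(widths) >= 3 and np.unique(centers).size > 1 and (
        np.unique(widths).size > 1
    ):
        tau, tau_p = width_rank_tau(widths, centers)
    else:
        tau, tau_p = float("nan"), float("nan")
    return {
        "n_units": table.n_units,
        "n_selected": int(selectivity["selected"].sum()),
        "selectivity": selectivity,
        "pooled_curves": pooled,
        "curve_centers": centers,
        "curve_fwhms": widths,
        "tau": tau,
        "tau_p": tau_p,
    }


@dataclass(frozen=True)
class SVMResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    wilcoxon_p: float
    n_folds: int


def svm_first_vs_rest(
    responses: np.ndarray,
    ordinality: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> SVMResult:
    """Linear SVM decoding of "first" versus all other ordinalities.

    ``responses`` is (n_units, n_images) from a fresh image set (disjoint
    from the screening images).  The majority "rest" class is subsampled
    to match the "first" class so chance is 0.5, then stratified k-fold
    cross-validation yields per-fold balanced accuracies, compared against
    chance with a one-tailed Wilcoxon signed-rank test.  With 5 folds the
    smallest attainable p is 1/32.
    """
    y_all = (np.asarray(ordinality) == 1).astype(int)
    if y_all.all() or not y_all.any():
        raise ValueError("need both 'first' and 'rest' classes present")
    rng = np.random.default_rng(seed)
    first_idx = np.flatnonzero(y_all == 1)
    rest_idx = np.flatnonzero(y_all == 0)
    keep_rest = rng.choice(rest_idx, size=min(first_idx.size, rest_idx.size),
                           replace=False)
    idx = np.sort(np.concatenate([first_idx, keep_rest]))
    X = np.asarray(responses, dtype=np.float64).T[idx]
    y = y_all[idx]
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    accs = []
    for train, test in cv.split(X, y):
        if np.unique(y[test]).size < 2 or np.unique(y[train]).size < 2:
            raise ValueError("a fold is missing a class; reduce n_folds")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        accs.append(balanced_accuracy_score(y[test], clf.predict(X[test])))
    accs = np.asarray(accs)
    diffs = accs - 0.5
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(diffs, alternative="greater").pvalue)
    return SVMResult(accs, float(accs.mean()), p, n_folds)
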