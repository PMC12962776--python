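"""Region-level group statistics on pooled pRF fits.

Sites from all participants are pooled within a cortical region (parietal
or premotor).  Three analyses are provided:

* ``width_trend_test`` — Spearman correlation of tuning width (FWHM)
  against preferred ordinality, with a one-tailed permutation test.
  Because functional voxels are upsampled to anatomical space, nearby
  sites can descend from the same acquired voxel and are not independent;
  the permutation therefore shuffles whole upsampling groups, keeping
  sites that share a source voxel together.
* ``coverage_by_rank`` — the fraction of a participant's included sites
  whose preferred ordinality falls in each rank bin 1..7.
* ``condition_agreement`` — per-cluster Pearson correlation of preferred
  ordinality between the two stimulus configurations, with
  Benjamini–Hochberg FDR control across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "width_trend_test",
    "coverage_by_rank",
    "condition_agreement",
    "TrendResult",
]

REQUIRED_COLUMNS = ("participant_id", "region", "site_id",
                    "preferred_ordinality", "fwhm")


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p_one_tailed: float
    n_sites: int
    n_groups: int
    permutation_level: str  # "group" or "site"


def _region_frame(table: pd.DataFrame, region: str) -> pd.DataFrame:
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValueError(f"no sites in region {region!r}")
    return sub


def width_trend_test(
    table: pd.DataFrame,
    region: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TrendResult:
    """One-tailed permutation Spearman test of FWHM increasing with rank.

    ``rho`` is the site-level Spearman correlation of fwhm against
    preferred_ordinality.  The null distribution permutes the
    preferred-ordinality values in blocks defined by ``upsampling_group``
    (all sites descending from one acquired voxel move together), which
    keeps the test valid under group-level exchangeability.  Groups of
    unequal size (e.g. after site exclusion) are handled by shuffling
    blocks within same-size strata, which preserves exchangeability
    exactly.  When the column is absent the test falls back to site-level
    permutation with a warning (risking anticonservative p-values if
    sites are upsampled).

    The p-value is (1 + #{rho_perm >= rho_obs}) / (n_perm + 1), hence never
    below 1/(n_perm + 1).
    """
    sub = _region_frame(table, region)
    pref = sub["preferred_ordinality"].to_numpy(dtype=float)
    fwhm = sub["fwhm"].to_numpy(dtype=float)
    if np.unique(pref).size < 3:
        raise ValueError("need >= 3 distinct preferred ordinalities for a trend")
    rho = float(sps.spearmanr(pref, fwhm).statistic)
    rng = np.random.default_rng(seed)

    r_f = sps.rankdata(fwhm)
    r_p = sps.rankdata(pref)
    level = "group"
    if "upsampling_group" in sub.columns and sub["upsampling_group"].notna().all():
        groups = sub["upsampling_group"].to_numpy()
        order = np.argsort(groups, kind="stable")
        g_sorted = groups[order]
        _, starts, counts = np.unique(g_sorted, return_index=True,
                                      return_counts=True)
        n_groups = counts.size
        rp_aligned = r_p[order]
        rf_aligned = r_f[order]
        rf0 = rf_aligned - rf_aligned.mean()
        denom_f = np.sqrt((rf0**2).sum())
        # blocks shuffle within same-size strata, so each site count is
        # preserved and within-block structure moves as a unit
        perm_stats = np.empty(n_perm)
        if np.unique(counts).size == 1:
            blocks_p = rp_aligned.reshape(n_groups, int(counts[0]))
            for b in range(n_perm):
                shuffled = blocks_p[rng.permutation(n_groups)].ravel()
                s0 = shuffled - shuffled.mean()
                perm_stats[b] = (s0 @ rf0) / (np.sqrt((s0**2).sum()) * denom_f)
        else:
            strata = {}
            for g in range(n_groups):
                strata.setdefault(int(counts[g]), []).append(g)
            block_slices = [slice(starts[g], starts[g] + counts[g])
                            for g in range(n_groups)]
            shuffled = np.empty_like(rp_aligned)
            for b in range(n_perm):
                for members in strata.values():
                    perm = rng.permutation(len(members))
                    for src, dst in zip(members, (members[j] for j in perm)):
                        shuffled[block_slices[dst]] = \
                            rp_aligned[block_slices[src]]
                s0 = shuffled - shuffled.mean()
                perm_stats[b] = (s0 @ rf0) / (np.sqrt((s0**2).sum()) * denom_f)
    else:
        warnings.warn(
            "upsampling_group missing: site-level permutation (anticonservative "
            "if sites are upsampled)"
        )
        level = "site"
        n_groups = pref.size
        rf0 = r_f - r_f.mean()
        denom_f = np.sqrt((rf0**2).sum())
        perm_stats = np.empty(n_perm)
        for b in range(n_perm):
            s = r_p[rng.permutation(pref.size)]
            s0 = s - s.mean()
            perm_stats[b] = (s0 @ rf0) / (np.sqrt((s0**2).sum()) * denom_f)
    p = (1.0 + np.sum(perm_stats >= rho)) / (n_perm + 1.0)
    return TrendResult(rho, float(p), int(pref.size), int(n_groups), level)


def coverage_by_rank(
    table: pd.DataFrame,
    participant: str,
    region: str,
    weights: str | None = None,
) -> np.ndarray:
    """Fraction of a participant's regional sites preferring each rank 1..7.

    Binning is half-open, [k, k+1) for k = 1..6, with [7, 7] closed, so a
    preferred ordinality of 3.5 counts toward bin 3.  Each site counts
    equally unless a ``weights`` column (e.g., per-site surface area) is
    named.  The seven fractions sum to 1.
    """
    sub = _region_frame(table, region)
    sub = sub[sub["participant_id"] == participant]
    if sub.empty:
        raise ValueError(f"no sites for participant {participant!r} in {region!r}")
    pref = sub["preferred_ordinality"].to_numpy(dtype=float)
    if np.any((pref < 1) | (pref > 7)):
        raise ValueError("preferred ordinality outside [1, 7] in coverage input")
    w = sub[weights].to_numpy(dtype=float) if weights else np.ones(pref.size)
    idx = np.minimum(np.floor(pref).astype(int), 7)
    out = np.zeros(7)
    np.add.at(out, idx - 1, w)
    return out / out.sum()


def condition_agreement(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    alpha: float = 0.05,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Per-cluster agreement of preferred ordinality across conditions.

    Inputs are fit tables with columns (site_id, cluster_id,
    preferred_ordinality); sites are matched by site_id within each
    cluster.  Returns one row per analyzable cluster with the Pearson r,
    raw p, BH-adjusted p across clusters, and a significance flag at the
    adjusted ``alpha``.  Clusters with fewer than ``min_sites`` matched
    sites are skipped with a warning.
    """
    merged = fits_a.merge(
        fits_b, on=["cluster_id", "site_id"], suffixes=("_a", "_b")
    )
    rows = []
    for cluster, grp in merged.groupby("cluster_id"):
        if len(grp) < min_sites:
            warnings.warn(
                f"cluster {cluster!r}: only {len(grp)} matched sites; skipped"
            )
            continue
        x = grp["preferred_ordinality_a"].to_numpy(dtype=float)
        y = grp["preferred_ordinality_b"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, 1.0
        else:
            res = sps.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"cluster_id": cluster, "n_sites": len(grp), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_fdr=pd.Series(dtype=float),
                          significant=pd.Series(dtype=bool))
    reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out
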