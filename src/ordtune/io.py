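"""Reading and writing the pipeline's tabular and volumetric formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .prf import SiteTimeSeries

__all__ = [
    "read_series_table",
    "write_series_table",
    "fits_to_frame",
    "load_nifti_series",
]


def read_series_table(path, condition: str | None = None) -> list:
    """Load sites from a long table (site_id, t, value[, condition]).

    CSV or Parquet by extension.  Returns a list of
    :class:`~ordtune.prf.SiteTimeSeries` ordered by site_id, samples
    ordered by t.
    """
    path = str(path)
    df = pd.read_parquet(path) if path.endswith(".parquet") else pd.read_csv(path)
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]
    out = []
    for sid, grp in df.sort_values("t").groupby("site_id", sort=True):
        label = (grp["condition"].iloc[0] if "condition" in grp.columns
                 else "other")
        out.append(SiteTimeSeries(str(sid), grp["value"].to_numpy(), str(label)))
    return out


def write_series_table(series_list, path) -> None:
    rows = []
    for s in series_list:
        for t, v in enumerate(s.samples):
            rows.append({"site_id": s.site_id, "t": t, "value": v,
                         "condition": s.condition_label})
    pd.DataFrame(rows).to_csv(path, index=False)


def fits_to_frame(fits) -> pd.DataFrame:
    """Per-site fit table: mu, sigma, fwhm, gain, offset, r2s, inclusion."""
    return pd.DataFrame([
        {
            "site_id": f.site_id,
            "mu": f.mu,
            "sigma": f.sigma,
            "fwhm": f.fwhm,
            "gain": f.gain,
            "offset": f.offset,
            "r2_within": f.r2_within,
            "r2_crossval": np.nan if f.r2_crossval is None else f.r2_crossval,
            "included": f.included,
            "flag": f.flag,
        }
        for f in fits
    ])


def load_nifti_series(path, mask_path=None) -> list:
    """Extract per-voxel series from a 4-D NIfTI volume.

    ``mask_path`` names a 3-D volume; voxels where it is nonzero are
    extracted (all voxels otherwise).  Site ids encode the voxel index as
    ``x_y_z``.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) != 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match volume")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    return [
        SiteTimeSeries("_".join(map(str, c)), data[tuple(c)]) for c in coords
    ]
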