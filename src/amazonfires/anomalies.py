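"""Standardized fire-count anomalies and exceedance-extent statistics.

Per-pixel annual counts are converted to z-scores against a reference period
(subtract the per-pixel reference mean, divide by the per-pixel reference
standard deviation), and the fire-season severity of a year is summarized as
the percent of valid area whose anomaly exceeds a threshold (2 SD by
default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = ["standardize", "extent_above"]


def standardize(counts: xr.DataArray, reference_years=None, ddof: int = 1) -> xr.DataArray:
    """Per-pixel z-scores of annual counts over a reference window.

    Pixels with zero variance over the reference years (which includes every
    never-burning pixel) cannot be standardized; they are masked (NaN) and
    their count is logged and stored in ``attrs['n_zero_variance']``.  The SD
    uses the sample (``ddof=1``) denominator by default.
    """
    years = counts["year"].to_numpy()
    if reference_years is None:
        reference_years = years
    reference_years = np.asarray(list(reference_years))
    if not np.isin(reference_years, years).all():
        missing = sorted(set(reference_years) - set(years))
        raise ValueError(f"reference years {missing} outside the data span")
    ref = counts.sel(year=reference_years).astype(float)
    mean = ref.mean(dim="year")
    sd = ref.std(dim="year", ddof=ddof)
    valid = sd > 0
    n_zero = int((~valid).sum())
    logger.info("standardize: masking %d zero-variance pixels", n_zero)
    z = xr.where(valid, (counts.astype(float) - mean) / sd.where(valid), np.nan)
    z = z.transpose("year", "row", "col")
    z.name = "z"
    z.attrs["n_zero_variance"] = n_zero
    z.attrs["ddof"] = ddof
    return z


def extent_above(z: xr.DataArray, threshold: float = 2.0,
                 denominator: str = "valid", total_pixels: int | None = None) -> pd.Series:
    """Percent of area with anomaly strictly above ``threshold``, per year.

    ``denominator='valid'`` (default) uses the fire-affected (unmasked)
    pixels as the area base; ``denominator='all'`` uses the whole grid (or
    ``total_pixels`` if given), which dilutes the percentage by pixels that
    never burn.  Both conventions are defensible for a biome-scale index, so
    both are exposed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    valid = np.isfinite(z).any(dim="year")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels to compute extent over")
    if denominator == "valid":
        denom = n_valid
    elif denominator == "all":
        denom = total_pixels if total_pixels is not None else z.sizes["row"] * z.sizes["col"]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    exceed = (z > threshold).sum(dim=("row", "col")).to_series()
    out = 100.0 * exceed / denom
    out.index = out.index.astype(int)
    out.name = f"pct_area_z_gt_{threshold:g}"
    return out
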