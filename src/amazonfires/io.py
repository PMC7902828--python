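"""Readers/writers for the pipeline's standard inputs and grid aggregation.

Active-fire detections travel as CSV tables (one row per satellite detection:
grid indices or lon/lat, ISO date, FRP in MW).  Land-surface products (tree
cover, annual deforestation) and annual count grids are :mod:`xarray`
datasets, persisted as NetCDF.  The study grid is north-up, row-major,
0-based, with half-open cell membership ``[x, x + cell)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["pixel_row", "pixel_col", "lon", "lat", "date", "frp_mw"]


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat analysis grid (~1 km cells).

    ``origin_lon``/``origin_lat`` locate the north-west corner; rows increase
    southwards.  ``cell_deg`` is the cell size in degrees (0.009° ≈ 1 km at
    the equator).
    """

    origin_lon: float = -74.0
    origin_lat: float = 5.0
    cell_deg: float = 0.009
    rows: int = 60
    cols: int = 60
    crs: str = "EPSG:4326"

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.rows}x{self.cols}")
        if self.cell_deg <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def lonlat_to_rowcol(self, lon, lat):
        """Half-open cell membership; returns (row, col) integer arrays."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_deg).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_deg).astype(int)
        return row, col

    def rowcol_to_lonlat(self, row, col):
        """Cell-centre coordinates."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_deg
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_deg
        return lon, lat

    def in_bounds(self, row, col):
        return (np.asarray(row) >= 0) & (np.asarray(row) < self.rows) & \
               (np.asarray(col) >= 0) & (np.asarray(col) < self.cols)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GridSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def read_detections(path, grid_spec: GridSpec, study_years=None) -> pd.DataFrame:
    """Read and validate an active-fire detection table.

    Rows failing validation (negative FRP, out-of-extent coordinates,
    out-of-study-year dates) are rejected; the rejection count is logged and
    stored in ``df.attrs['n_rejected']``.  Missing FRP is retained (NaN) for
    counting but excluded from intensity analyses downstream.
    """
    df = pd.read_csv(path)
    has_idx = {"pixel_row", "pixel_col"}.issubset(df.columns)
    has_ll = {"lon", "lat"}.issubset(df.columns)
    required = {"date", "frp_mw"}
    missing = required - set(df.columns)
    if missing or not (has_idx or has_ll):
        raise ValueError(
            f"detection table at {path} missing required columns: "
            f"{sorted(missing) or 'pixel_row/pixel_col or lon/lat'}")
    df["date"] = pd.to_datetime(df["date"])
    if not has_idx:
        row, col = grid_spec.lonlat_to_rowcol(df["lon"].to_numpy(), df["lat"].to_numpy())
        df["pixel_row"], df["pixel_col"] = row, col
    if not has_ll:
        lon, lat = grid_spec.rowcol_to_lonlat(df["pixel_row"].to_numpy(),
                                              df["pixel_col"].to_numpy())
        df["lon"], df["lat"] = lon, lat

    ok = grid_spec.in_bounds(df["pixel_row"].to_numpy(), df["pixel_col"].to_numpy())
    ok &= (df["frp_mw"].isna() | (df["frp_mw"] >= 0)).to_numpy()
    if study_years is not None:
        ok &= df["date"].dt.year.isin(list(study_years)).to_numpy()
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d invalid detection rows from %s", n_rejected, path)
    out = df.loc[ok, DETECTION_COLUMNS].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def write_detections(detections: pd.DataFrame, path) -> None:
    df = detections.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in DETECTION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.10g")


def rasterize_counts(detections: pd.DataFrame, years, grid_spec: GridSpec,
                     distinct_days: bool = False) -> xr.DataArray:
    """Per-pixel annual detection counts (or distinct detection days).

    With ``distinct_days`` the cell value is the number of calendar days with
    at least one detection — the fire-persistence measure — rather than the
    raw detection count.
    """
    years = list(years)
    df = detections.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    df = df[df["year"].isin(years)]
    if distinct_days:
        df = df.drop_duplicates(subset=["pixel_row", "pixel_col", "year", "date"])
    grid = np.zeros((len(years), grid_spec.rows, grid_spec.cols), dtype=np.int64)
    if len(df):
        yi = pd.Index(years).get_indexer(df["year"])
        np.add.at(grid, (yi, df["pixel_row"].to_numpy(), df["pixel_col"].to_numpy()), 1)
    return xr.DataArray(grid, dims=("year", "row", "col"),
                        coords={"year": years}, name="fire_counts")


def aggregate_to_grid(fine: xr.DataArray, grid_spec: GridSpec, statistic: str = "mean",
                      threshold: float | None = None) -> xr.DataArray:
    """Aggregate a fine-resolution raster to the analysis grid by block statistic.

    The fine raster's shape must be an integer multiple of the grid shape
    (e.g. 30 m cells inside 1 km cells).  ``statistic`` is ``"mean"`` or
    ``"fraction_above_threshold"``; NaN marks nodata and blocks that are all
    nodata come out masked (NaN).
    """
    if statistic not in ("mean", "fraction_above_threshold"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "fraction_above_threshold" and threshold is None:
        raise ValueError("fraction_above_threshold requires a threshold")
    fine_crs = fine.attrs.get("crs", grid_spec.crs)
    if fine_crs != grid_spec.crs:
        raise ValueError(f"CRS mismatch ({fine_crs} vs {grid_spec.crs}) and no "
                         "transform is configured")
    arr = np.asarray(fine, dtype=float)
    R, C = grid_spec.shape
    if arr.shape[0] % R or arr.shape[1] % C:
        raise ValueError(f"fine raster {arr.shape} does not evenly divide grid {R}x{C}")
    fr, fc = arr.shape[0] // R, arr.shape[1] // C
    blocks = arr.reshape(R, fr, C, fc).transpose(0, 2, 1, 3).reshape(R, C, fr * fc)
    if statistic == "fraction_above_threshold":
        blocks = np.where(np.isnan(blocks), np.nan, (blocks > threshold).astype(float))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks -> NaN
        out = np.nanmean(blocks, axis=-1)
    return xr.DataArray(out, dims=("row", "col"), name=statistic,
                        attrs={"crs": grid_spec.crs})


def save_raster(ds: xr.Dataset | xr.DataArray, path) -> None:
    """Persist a landscape or count grid as NetCDF (classic format)."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds.to_netcdf(path, engine="scipy")


def load_raster(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def annual_deforestation_km2(landscape: xr.Dataset) -> pd.Series:
    """Biome-total deforested area per year (km²) from per-pixel annual rates.

    Each pixel is 1 km², so the sum of per-pixel annual clearing fractions is
    directly an area.
    """
    rate = landscape["annual_defor_rate"]
    s = (rate / 100.0).sum(dim=("row", "col")).to_series()
    s.index = s.index.astype(int)
    s.name = "defor_km2"
    return s
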