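"""Rule-based classification of active fires into three landscape fire types.

Each pixel-year with detections is assigned one of three labels from fire
persistence and the pixel's land-cover history:

* **deforestation** — persistent burning (≥ 2 distinct detection days) on a
  pixel undergoing active clearing (annual deforestation rate ≥ 5%), the
  signature of piled slash burned repeatedly;
* **forest** — short-lived burning (≤ 3 days) under largely intact canopy
  (year-2000 tree cover ≥ 70%, cumulative clearing since 2001 ≤ 20%),
  i.e. understory fire;
* **maintenance** — everything else: pasture/cropland upkeep burns that
  consume light fuels in a single day.

The deforestation and forest conditions can both hold for 2–3-day pixels;
by default the deforestation rule wins (rules applied in the order above),
with the precedence configurable for sensitivity analysis.  The unit of
classification is the pixel-year: all detections at one pixel in one year
share a label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ClassificationThresholds",
    "FIRE_TYPES",
    "persistence",
    "persistence_table",
    "classify_pixel_year",
    "classify_all",
    "annual_type_counts",
]

FIRE_TYPES = ("deforestation", "maintenance", "forest")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the three-rule classifier (percent units)."""

    min_persistent_days: int = 2
    max_forest_days: int = 3
    min_defor_rate: float = 5.0
    min_tree_cover: float = 70.0
    max_cum_defor: float = 20.0

    def __post_init__(self):
        if self.min_persistent_days < 1 or self.max_forest_days < 1:
            raise ValueError("day thresholds must be >= 1")
        for name in ("min_defor_rate", "min_tree_cover", "max_cum_defor"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


def persistence_table(detections: pd.DataFrame, months=None) -> pd.DataFrame:
    """Distinct detection days per pixel-year.

    ``months`` optionally restricts counting to a dry-season window (an
    iterable of month numbers); the default window is the calendar year.
    Returns columns ``pixel_row, pixel_col, year, n_days``.
    """
    df = detections[["pixel_row", "pixel_col", "date"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    if months is not None:
        df = df[df["date"].dt.month.isin(list(months))]
    df["year"] = df["date"].dt.year
    tab = (df.drop_duplicates(["pixel_row", "pixel_col", "year", "date"])
             .groupby(["pixel_row", "pixel_col", "year"], as_index=False)
             .size().rename(columns={"size": "n_days"}))
    return tab


def persistence(detections: pd.DataFrame, pixel: tuple[int, int], year: int,
                months=None) -> int:
    """Distinct detection days at one pixel in one year (0 if no fires)."""
    tab = persistence_table(detections, months=months)
    hit = tab[(tab.pixel_row == pixel[0]) & (tab.pixel_col == pixel[1]) &
              (tab.year == year)]
    return int(hit.n_days.iloc[0]) if len(hit) else 0


def classify_pixel_year(n_days: int, tree_cover: float, annual_rate: float,
                        cum_defor: float,
                        thresholds: ClassificationThresholds = ClassificationThresholds(),
                        precedence: str = "deforestation_first") -> str:
    """Label one pixel-year; see the module docstring for the rules."""
    if n_days < 1:
        raise ValueError("classification requires at least one detection day")
    lab = _classify_arrays(np.array([n_days]), np.array([float(tree_cover)]),
                           np.array([float(annual_rate)]), np.array([float(cum_defor)]),
                           thresholds, precedence)
    return str(lab[0])


def _classify_arrays(n_days, tree_cover, annual_rate, cum_defor, thr, precedence):
    is_defor = (n_days >= thr.min_persistent_days) & (annual_rate >= thr.min_defor_rate)
    is_forest = (n_days <= thr.max_forest_days) & (tree_cover >= thr.min_tree_cover) & \
                (cum_defor <= thr.max_cum_defor)
    if precedence == "deforestation_first":
        conds = [is_defor, is_forest]
        labels = ["deforestation", "forest"]
    elif precedence == "forest_first":
        conds = [is_forest, is_defor]
        labels = ["forest", "deforestation"]
    else:
        raise ValueError(f"unknown precedence {precedence!r}")
    return np.select(conds, labels, default="maintenance")


def classify_all(detections: pd.DataFrame, landscape: xr.Dataset,
                 thresholds: ClassificationThresholds = ClassificationThresholds(),
                 precedence: str = "deforestation_first",
                 months=None, on_missing: str = "error") -> pd.DataFrame:
    """Label every detection via its pixel-year.

    ``landscape`` must provide ``tree_cover_2000 (row, col)`` and
    ``annual_defor_rate`` / ``cum_defor`` ``(year, row, col)``.  Detections on
    pixel-years without landscape coverage raise by default
    (``on_missing='maintenance'`` labels them maintenance with a warning).
    Returns the detections with a ``fire_type`` column (and ``n_days``).
    """
    df = detections.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    tab = persistence_table(df, months=months)
    df = df.merge(tab, on=["pixel_row", "pixel_col", "year"], how="left")
    # detections outside the persistence window carry no label basis
    if df["n_days"].isna().any():
        df = df.dropna(subset=["n_days"]).reset_index(drop=True)
    df["n_days"] = df["n_days"].astype(int)

    rows = df["pixel_row"].to_numpy()
    cols = df["pixel_col"].to_numpy()
    years = df["year"].to_numpy()
    land_years = landscape["annual_defor_rate"]["year"].to_numpy()
    in_land = np.isin(years, land_years) & \
        (rows >= 0) & (rows < landscape.sizes["row"]) & \
        (cols >= 0) & (cols < landscape.sizes["col"])
    if not in_land.all():
        n_bad = int((~in_land).sum())
        if on_missing == "error":
            raise ValueError(f"{n_bad} detections on pixel-years without landscape records")
        import logging
        logging.getLogger(__name__).warning(
            "%d detections lack landscape records; labelled maintenance", n_bad)

    safe_rows = np.clip(rows, 0, landscape.sizes["row"] - 1)
    safe_cols = np.clip(cols, 0, landscape.sizes["col"] - 1)
    yi = np.searchsorted(land_years, np.clip(years, land_years.min(), land_years.max()))
    tree = landscape["tree_cover_2000"].to_numpy()[safe_rows, safe_cols]
    rate = landscape["annual_defor_rate"].to_numpy()[yi, safe_rows, safe_cols]
    cum = landscape["cum_defor"].to_numpy()[yi, safe_rows, safe_cols]

    labels = _classify_arrays(df["n_days"].to_numpy(), tree, rate, cum,
                              thresholds, precedence)
    labels = np.where(in_land, labels, "maintenance")
    df["fire_type"] = labels
    return df


def annual_type_counts(labeled: pd.DataFrame, years=None) -> pd.DataFrame:
    """Annual detection counts per fire type with shares and type ratios.

    Shares are percentages of the annual total; the ratio columns give
    deforestation:forest and deforestation:maintenance counts as percentages,
    the decoupling-relevant composition diagnostics.
    """
    df = labeled.copy()
    if "year" not in df.columns:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    counts = (df.groupby(["year", "fire_type"]).size().unstack(fill_value=0)
                .reindex(columns=list(FIRE_TYPES), fill_value=0))
    if years is not None:
        counts = counts.reindex(list(years), fill_value=0)
    counts["total"] = counts[list(FIRE_TYPES)].sum(axis=1)
    total = counts["total"].replace(0, np.nan)
    for t in FIRE_TYPES:
        counts[f"share_{t}"] = 100.0 * counts[t] / total
    counts["ratio_defor_forest"] = 100.0 * counts["deforestation"] / counts["forest"].replace(0, np.nan)
    counts["ratio_defor_maintenance"] = (100.0 * counts["deforestation"] /
                                         counts["maintenance"].replace(0, np.nan))
    counts.index.name = "year"
    return counts
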