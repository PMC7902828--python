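import numpy as np
import pandas as pd
import pytest
import xarray as xr

from amazonfires.synthetic import (SyntheticConfig, generate_fire_seasons,
                                   generate_landscape)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(grid_rows=20, grid_cols=20, seed=42,
                           base_detections_per_pixel=1.5)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_season(small_config, small_landscape):
    """(detections, truth) for the small seeded synthetic study."""
    return generate_fire_seasons(small_config, small_landscape)


def make_landscape(years, tree_cover, annual_rate, cum_defor):
    """Hand-built single-stratum landscape: every pixel shares one history.

    ``tree_cover`` is (row, col); the two rate arrays map year -> scalar.
    """
    tree = np.asarray(tree_cover, dtype=float)
    R, C = tree.shape
    years = list(years)
    rate = np.stack([np.full((R, C), float(annual_rate[y])) for y in years])
    cum = np.stack([np.full((R, C), float(cum_defor[y])) for y in years])
    return xr.Dataset(
        {
            "tree_cover_2000": (("row", "col"), tree),
            "annual_defor_rate": (("year", "row", "col"), rate),
            "cum_defor": (("year", "row", "col"), cum),
        },
        coords={"year": years},
    )


def detections_frame(rows, cols, dates, frp=None):
    rows = np.asarray(rows)
    frp = np.full(len(rows), 10.0) if frp is None else np.asarray(frp, dtype=float)
    return pd.DataFrame({
        "pixel_row": rows,
        "pixel_col": np.asarray(cols),
        "date": pd.to_datetime(list(dates)),
        "frp_mw": frp,
    })
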