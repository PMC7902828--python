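"""EOF / principal-component decomposition of standardized fire-count maps.

The annual anomaly fields of one fire type form a years × pixels matrix
(valid pixels only).  Because the study has far fewer years (~17) than
pixels, the decomposition runs through the thin SVD of that matrix:
explained-variance fractions come from the squared singular values, EOFs are
the right singular vectors (spatial patterns) and PCs the projections of
each year onto them (time coefficients).  No rotation is applied.

Sign gauge: each EOF is scaled so its largest-|loading| element is positive,
and the PC is flipped accordingly, which makes decompositions deterministic
across platforms while leaving every EOFₖ·PCₖ product invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["ModeDecomposition", "decompose", "eof_sign_maps", "variance_table"]


@dataclass
class ModeDecomposition:
    """EOF maps, PC series and variance spectrum for one fire type."""

    fire_type: str | None
    eofs: np.ndarray             # (n_modes, n_valid) orthonormal spatial patterns
    pcs: pd.DataFrame            # year x mode time coefficients
    explained: np.ndarray        # percent of total variance per mode
    singular_values: np.ndarray
    valid_mask: np.ndarray       # (row, col) bool
    shape: tuple[int, int]

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def eof_map(self, mode: int) -> xr.DataArray:
        """Spatial pattern of one mode as a grid (NaN outside the mask)."""
        grid = np.full(self.shape, np.nan)
        grid[self.valid_mask] = self.eofs[mode]
        return xr.DataArray(grid, dims=("row", "col"), name=f"eof_{mode + 1}")

    def reconstruct(self) -> np.ndarray:
        """Years × valid-pixels matrix rebuilt from all retained modes."""
        return (self.pcs.to_numpy() @ self.eofs)


def decompose(z: xr.DataArray, fire_type: str | None = None,
              n_modes: int | None = None) -> ModeDecomposition:
    """PCA of a standardized (year, row, col) anomaly stack.

    The valid-pixel mask (finite values) must be identical across years.
    ``n_modes`` defaults to all modes (min(n_years, n_valid)); a larger
    request is clipped with a warning.
    """
    z = z.transpose("year", "row", "col")
    finite = np.isfinite(z.to_numpy())
    mask = finite[0]
    if not (finite == mask[None]).all():
        raise ValueError("valid-pixel mask varies across years; standardize first")
    if mask.sum() == 0:
        raise ValueError("no valid pixels")
    X = z.to_numpy()[:, mask]  # years x valid pixels
    years = z["year"].to_numpy().astype(int)

    u, sv, vt = np.linalg.svd(X, full_matrices=False)
    max_modes = len(sv)
    if n_modes is None:
        n_modes = max_modes
    elif n_modes > max_modes:
        warnings.warn(f"n_modes={n_modes} exceeds available {max_modes}; clipped")
        n_modes = max_modes

    # deterministic sign: largest-|loading| element of each EOF made positive
    for k in range(max_modes):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1

    total = float((sv ** 2).sum())
    explained = 100.0 * sv ** 2 / total if total > 0 else np.zeros_like(sv)
    pcs = pd.DataFrame(u[:, :n_modes] * sv[:n_modes], index=pd.Index(years, name="year"),
                       columns=[f"PC{k + 1}" for k in range(n_modes)])
    return ModeDecomposition(fire_type, vt[:n_modes], pcs, explained[:n_modes],
                             sv[:n_modes], mask, z.shape[1:])


def eof_sign_maps(decomp: ModeDecomposition, modes) -> xr.DataArray:
    """Per-pixel sign ({-1, 0, +1}) of the requested EOF loadings.

    Sign maps strip amplitude and expose the spatial contrast structure of
    each mode (e.g. north–south opposition of fire activity).
    """
    modes = list(modes)
    for m in modes:
        if not 0 <= m < decomp.eofs.shape[0]:
            raise ValueError(f"mode {m} not in decomposition")
    grids = np.full((len(modes),) + decomp.shape, np.nan)
    for i, m in enumerate(modes):
        g = np.full(decomp.shape, np.nan)
        g[decomp.valid_mask] = np.sign(decomp.eofs[m])
        grids[i] = g
    return xr.DataArray(grids, dims=("mode", "row", "col"),
                        coords={"mode": [m + 1 for m in modes]}, name="eof_sign")


def variance_table(decomps: dict[str, ModeDecomposition]) -> pd.DataFrame:
    """Tidy explained-variance table: one row per (fire type, mode)."""
    rows = []
    for name, d in decomps.items():
        cum = d.cumulative
        for k, lam in enumerate(d.explained):
            rows.append((name, k + 1, float(lam), float(cum[k])))
    return pd.DataFrame(rows, columns=["fire_type", "mode", "explained_pct",
                                       "cumulative_pct"])
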