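"""Gaussian smoothing of per-gene noise measurements over Crick space.

Cell-to-cell protein variability (the coefficient of variation, CV) is
measured per gene; to see how it varies with transcription and translation
rates the scattered per-gene values are averaged onto a regular grid in
log10(beta_m) x log10(beta_p) with Gaussian weights:

    cv_hat(x, y) = sum_i w_i cv_i / sum_i w_i

Nodes supported by too little data (sum of weights below a cutoff) are left
undefined, so contours are only drawn where the gene density warrants them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyTableError, InvalidParameterError

__all__ = ["SmoothedSurface", "smooth_cv_surface"]


@dataclass(frozen=True)
class SmoothedSurface:
    """Smoothed CV surface on a log10-rate lattice.

    ``cv_hat`` is NaN at nodes whose total Gaussian weight ``weight_sum``
    falls below ``density_cutoff``.
    """

    grid_beta_m: np.ndarray  # log10 beta_m node coordinates, shape (nx,)
    grid_beta_p: np.ndarray  # log10 beta_p node coordinates, shape (ny,)
    cv_hat: np.ndarray       # shape (ny, nx)
    weight_sum: np.ndarray   # shape (ny, nx)
    sigma_smooth: tuple[float, float]
    density_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (log10_beta_m, log10_beta_p, cv_hat, weight_sum)."""
        xx, yy = np.meshgrid(self.grid_beta_m, self.grid_beta_p)
        return pd.DataFrame(
            {
                "log10_beta_m": xx.ravel(),
                "log10_beta_p": yy.ravel(),
                "cv_hat": self.cv_hat.ravel(),
                "weight_sum": self.weight_sum.ravel(),
            }
        )


def smooth_cv_surface(
    rates: pd.DataFrame,
    cv: np.ndarray,
    sigma_smooth: tuple[float, float] | None = None,
    density_cutoff: float = 200.0,
    grid_shape: tuple[int, int] = (50, 50),
) -> SmoothedSurface:
    """Weighted-average CV surface over log10 Crick space.

    ``cv`` must align with ``rates`` row-for-row. The smoothing width
    defaults to one fifth of the data range, taken per axis in log10
    coordinates. Weights carry the Gaussian normalization prefactor
    1/sqrt(2*pi*sigma_x*sigma_y); it cancels in the weighted mean but sets
    the scale of ``weight_sum`` against ``density_cutoff``.
    """
    cv = np.asarray(cv, dtype=float)
    if len(rates) == 0:
        raise EmptyTableError("rates table is empty")
    if cv.shape[0] != len(rates):
        raise InvalidParameterError("cv must align with the rates table")
    x = np.log10(rates["beta_m"].to_numpy(float))
    y = np.log10(rates["beta_p"].to_numpy(float))

    if sigma_smooth is None:
        sigma_smooth = (np.ptp(x) / 5.0, np.ptp(y) / 5.0)
    sx, sy = sigma_smooth
    if not (sx > 0 and sy > 0):
        raise InvalidParameterError("smoothing widths must be strictly positive")

    nx, ny = grid_shape
    gx = np.linspace(x.min(), x.max(), nx)
    gy = np.linspace(y.min(), y.max(), ny)

    prefactor = 1.0 / np.sqrt(2.0 * np.pi * sx * sy)
    # (ny, nx, n_genes) would be large; accumulate over grid rows instead
    dx2 = ((gx[:, None] - x[None, :]) / sx) ** 2  # (nx, n)
    weight_sum = np.empty((ny, nx))
    cv_hat = np.full((ny, nx), np.nan)
    for j, yj in enumerate(gy):
        dy2 = ((yj - y) / sy) ** 2  # (n,)
        w = prefactor * np.exp(-0.5 * (dx2 + dy2[None, :]))  # (nx, n)
        ws = w.sum(axis=1)
        weight_sum[j] = ws
        ok = ws > 0
        cv_hat[j, ok] = (w[ok] @ cv) / ws[ok]

    mask = weight_sum < density_cutoff
    cv_hat[mask] = np.nan
    if np.all(mask):
        import warnings

        warnings.warn("every grid node falls below the density cutoff", stacklevel=2)
    return SmoothedSurface(
        grid_beta_m=gx,
        grid_beta_p=gy,
        cv_hat=cv_hat,
        weight_sum=weight_sum,
        sigma_smooth=(float(sx), float(sy)),
        density_cutoff=density_cutoff,
    )
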