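"""Spatial correlation structures for the spatially extended models.

The spatial effect s ~ N(0, S sigma_s2) enters the model with a
correlation matrix S over plots.  Three structures are supported:

* isotropic exponential, S_ij = exp(-D_ij / phi), with D the
  centre-to-centre distance in metres and phi a range parameter;
* separable AR1 x AR1 over the grid, S_ij = rho_range^|dr| * rho_col^|dc|;
* a user-supplied matrix, validated for symmetry, unit diagonal and
  positive semidefiniteness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geometry import FieldLayout

__all__ = ["SpatialStructure", "SpatialSpec", "build_spatial_correlation"]

PSD_TOL = 1e-8


class SpatialStructure(str, enum.Enum):
    EXPONENTIAL_ISO = "exponential"
    AR1xAR1 = "ar1xar1"
    USER_MATRIX = "user"


@dataclass(frozen=True)
class SpatialSpec:
    structure: SpatialStructure
    phi: float | None = None
    rho_range: float | None = None
    rho_col: float | None = None
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure is SpatialStructure.EXPONENTIAL_ISO:
            if self.phi is None or self.phi < 0:
                raise ValueError("exponential structure requires phi >= 0")
        elif self.structure is SpatialStructure.AR1xAR1:
            for rho in (self.rho_range, self.rho_col):
                if rho is None or not (-1 < rho < 1):
                    raise ValueError("AR1xAR1 requires rho_range, rho_col in (-1, 1)")
        elif self.matrix is None:
            raise ValueError("user structure requires a matrix")


def _validate(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("spatial matrix must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValueError("spatial matrix must have unit diagonal")
    if np.abs(S).max() > 1 + 1e-8:
        raise ValueError("spatial correlations must lie in [-1, 1]")
    w = np.linalg.eigvalsh((S + S.T) / 2.0)
    if w.min() < -PSD_TOL:
        raise ValueError(f"spatial matrix not PSD (min eigenvalue {w.min():.3g})")
    return (S + S.T) / 2.0


def build_spatial_correlation(layout: FieldLayout, spec: SpatialSpec) -> np.ndarray:
    """n x n validated spatial correlation matrix for the layout."""
    if spec.structure is SpatialStructure.USER_MATRIX:
        S = np.asarray(spec.matrix, dtype=float)
        if S.shape != (layout.n_plots, layout.n_plots):
            raise ValueError("user matrix shape does not match the layout")
        return _validate(S)
    if spec.structure is SpatialStructure.EXPONENTIAL_ISO:
        if spec.phi == 0:
            return np.eye(layout.n_plots)
        S = np.exp(-layout.distance_matrix() / spec.phi)
    else:
        dr = np.abs(layout.range_idx[:, None] - layout.range_idx[None, :])
        dc = np.abs(layout.col_idx[:, None] - layout.col_idx[None, :])
        S = (spec.rho_range ** dr) * (spec.rho_col ** dc)
    return _validate(S)
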