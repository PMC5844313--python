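"""Field geometry and competition incidence matrices.

A field trial is a rectangular grid of plots indexed by Range and Column
(both 1-based).  Plots are rectangles of ``plot_width`` x ``plot_length``
metres; in single-row clonal trials the *long* edge of the plot is usually
shared between adjacent Ranges, so the centre-to-centre spacing across
Ranges equals ``plot_width`` and the spacing across Columns equals
``plot_length``.  Competition from a neighbouring plot is a weight in
[0, 1] that decays with the distance D between plot centres:

* ``NN_LONG`` -- weight 1 for long-edge neighbours only;
* ``NN_ALL``  -- 1 / 0.5 / 0.2 for long-edge / short-edge / diagonal
  neighbours;
* ``FD``      -- fast decay, w = k / (D + k - 1);
* ``SD``      -- slow decay, w = 1 / (c + b**(1/D)), optionally truncated
  to zero beyond ``dmax`` metres.

FD with k = 1 is exactly w = 1/D, and k = 0.4 closely tracks 1/D**2.

From a weight function three incidence matrices are built for a layout of
n plots and g distinct clones:

* ``Z1`` (n x g): plot -> its own clone (one 1 per row);
* ``Z2`` (n x g): plot -> neighbouring clones, entries are summed weights;
* ``II`` (n x n): plot -> neighbouring plots, zero diagonal.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LongEdgeAxis",
    "FunctionKind",
    "FieldLayout",
    "CompetitionFunction",
    "IncidenceSet",
    "plot_center_distance",
    "fd_weight",
    "sd_weight",
    "nn_weight",
    "build_incidence",
]


class LongEdgeAxis(str, enum.Enum):
    """Which pair of neighbours shares the long plot edge."""

    BETWEEN_RANGES = "between_ranges"
    BETWEEN_COLUMNS = "between_columns"


class FunctionKind(str, enum.Enum):
    NN_LONG = "nn_long"
    NN_ALL = "nn_all"
    FD = "fd"
    SD = "sd"


# NN_ALL incidences for long-edge, short-edge and diagonal adjacency.
NN_ALL_WEIGHTS = (1.0, 0.5, 0.2)


@dataclass(frozen=True)
class FieldLayout:
    """Plot positions and clone assignment of one trial.

    ``range_idx`` and ``col_idx`` are 1-based grid indices; each
    (Range, Column) cell holds at most one plot.  Missing cells are
    simply absent plots and contribute no competition.
    """

    plot_ids: np.ndarray
    range_idx: np.ndarray
    col_idx: np.ndarray
    clone_ids: np.ndarray
    plot_width: float = 1.0
    plot_length: float = 2.0
    long_edge_axis: LongEdgeAxis = LongEdgeAxis.BETWEEN_RANGES

    def __post_init__(self) -> None:
        object.__setattr__(self, "plot_ids", np.asarray(self.plot_ids))
        object.__setattr__(self, "range_idx", np.asarray(self.range_idx, dtype=int))
        object.__setattr__(self, "col_idx", np.asarray(self.col_idx, dtype=int))
        object.__setattr__(self, "clone_ids", np.asarray(self.clone_ids, dtype=object))
        n = len(self.plot_ids)
        if n < 1:
            raise ValueError("a layout needs at least one plot")
        for arr, name in [(self.range_idx, "range_idx"), (self.col_idx, "col_idx")]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} plots")
            if (arr < 1).any():
                raise ValueError(f"{name} must be 1-based positive integers")
        if len(self.clone_ids) != n:
            raise ValueError("clone_ids length mismatch")
        cells = set(zip(self.range_idx.tolist(), self.col_idx.tolist()))
        if len(cells) != n:
            raise ValueError("duplicate (Range, Column) cell in layout")
        if not (self.plot_width > 0 and self.plot_length > 0):
            raise ValueError("plot dimensions must be positive")
        if self.plot_length < self.plot_width:
            raise ValueError("plot_length must be >= plot_width (long edge)")

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def coordinates(self) -> np.ndarray:
        """(n, 2) plot-centre coordinates in metres.

        The spacing across the axis sharing the long edge equals
        ``plot_width``; across the other axis it equals ``plot_length``.
        """
        if self.long_edge_axis is LongEdgeAxis.BETWEEN_RANGES:
            step_range, step_col = self.plot_width, self.plot_length
        else:
            step_range, step_col = self.plot_length, self.plot_width
        return np.column_stack(
            [self.range_idx * step_range, self.col_idx * step_col]
        ).astype(float)

    def distance_matrix(self) -> np.ndarray:
        xy = self.coordinates()
        diff = xy[:, None, :] - xy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


@dataclass(frozen=True)
class CompetitionFunction:
    """A distance-to-weight rule; see module docstring for the families."""

    kind: FunctionKind
    k: float | None = None
    c: float | None = None
    b: float | None = None
    dmax: float = math.inf

    def __post_init__(self) -> None:
        if self.dmax <= 0:
            raise ValueError("dmax must be positive")
        if self.kind is FunctionKind.FD:
            if self.k is None or self.k <= 0:
                raise ValueError("FD requires k > 0")
        elif self.kind is FunctionKind.SD:
            if self.b is None or not (0 < self.b < 1):
                raise ValueError("SD requires 0 < b < 1")
            c = 1.0 - self.b if self.c is None else self.c
            if abs(c + self.b - 1.0) > 1e-12:
                raise ValueError("SD requires c + b = 1")
            object.__setattr__(self, "c", c)

    def label(self) -> str:
        if self.kind is FunctionKind.FD:
            return f"FD(k={self.k:g})"
        if self.kind is FunctionKind.SD:
            return f"SD(b={self.b:g},Dmax={self.dmax:g})"
        return {FunctionKind.NN_LONG: "NN-long", FunctionKind.NN_ALL: "NN-all"}[self.kind]

    def weights(self, layout: FieldLayout) -> np.ndarray:
        """n x n matrix of pairwise competition weights, zero diagonal."""
        n = layout.n_plots
        if self.kind in (FunctionKind.NN_LONG, FunctionKind.NN_ALL):
            dr = np.abs(layout.range_idx[:, None] - layout.range_idx[None, :])
            dc = np.abs(layout.col_idx[:, None] - layout.col_idx[None, :])
            if layout.long_edge_axis is LongEdgeAxis.BETWEEN_RANGES:
                d_long, d_short = dr, dc
            else:
                d_long, d_short = dc, dr
            w = np.zeros((n, n))
            w_long, w_short, w_diag = NN_ALL_WEIGHTS
            w[(d_long == 1) & (d_short == 0)] = w_long
            if self.kind is FunctionKind.NN_ALL:
                w[(d_long == 0) & (d_short == 1)] = w_short
                w[(d_long == 1) & (d_short == 1)] = w_diag
            return w
        D = layout.distance_matrix()
        off = ~np.eye(n, dtype=bool)
        w = np.zeros((n, n))
        if self.kind is FunctionKind.FD:
            w[off] = fd_weight(self.k, D[off])
        else:
            w[off] = sd_weight(self.c, self.b, D[off], self.dmax)
        w[D > self.dmax] = 0.0
        np.fill_diagonal(w, 0.0)
        return w


@dataclass(frozen=True)
class IncidenceSet:
    """Z1, Z2 (n x g) and II (n x n) for one layout and weight rule."""

    Z1: np.ndarray
    Z2: np.ndarray
    II: np.ndarray
    clone_index: dict = field(default_factory=dict)

    @property
    def n_plots(self) -> int:
        return self.Z1.shape[0]

    @property
    def n_clones(self) -> int:
        return self.Z1.shape[1]


def plot_center_distance(layout: FieldLayout, i: int, j: int) -> float:
    """Euclidean distance in metres between the centres of plots i and j."""
    n = layout.n_plots
    for idx in (i, j):
        if not (0 <= idx < n):
            raise IndexError(f"plot index {idx} out of range for {n} plots")
    xy = layout.coordinates()
    return float(np.hypot(*(xy[i] - xy[j])))


def fd_weight(k: float, D):
    """Fast-decay weight k / (D + k - 1); equals 1 at D = 1."""
    D = np.asarray(D, dtype=float)
    if (D <= 0).any():
        raise ValueError("distance must be positive")
    if ((D + k - 1) <= 0).any():
        raise ValueError("FD undefined where D + k - 1 <= 0")
    out = k / (D + k - 1.0)
    return float(out) if out.ndim == 0 else out


def sd_weight(c: float, b: float, D, dmax: float = math.inf):
    """Slow-decay weight 1 / (c + b**(1/D)), zero beyond ``dmax``.

    A modified logistic in 1/D: equals 1 at D = 1 (since c + b = 1) and
    decays towards 1 / (c + 1) as D grows, so the intensity stays high
    until the hard cutoff.
    """
    if not (0 < b < 1):
        raise ValueError("SD requires 0 < b < 1")
    if abs(c + b - 1.0) > 1e-12:
        raise ValueError("SD requires c + b = 1")
    D = np.asarray(D, dtype=float)
    if (D <= 0).any():
        raise ValueError("distance must be positive")
    out = np.where(D <= dmax, 1.0 / (c + b ** (1.0 / D)), 0.0)
    return float(out) if out.ndim == 0 else out


def nn_weight(layout: FieldLayout, i: int, j: int, variant: str = "all") -> float:
    """Nearest-neighbour incidence between plots i and j.

    ``variant='long_only'`` gives 1 to long-edge neighbours and 0 to all
    others; ``variant='all'`` gives 1 / 0.5 / 0.2 to long-edge /
    short-edge / diagonal neighbours.
    """
    if i == j:
        raise ValueError("nn_weight is undefined for a plot with itself")
    dr = abs(int(layout.range_idx[i]) - int(layout.range_idx[j]))
    dc = abs(int(layout.col_idx[i]) - int(layout.col_idx[j]))
    if layout.long_edge_axis is LongEdgeAxis.BETWEEN_RANGES:
        d_long, d_short = dr, dc
    else:
        d_long, d_short = dc, dr
    w_long, w_short, w_diag = NN_ALL_WEIGHTS
    if d_long == 1 and d_short == 0:
        return w_long
    if variant == "long_only":
        return 0.0
    if d_long == 0 and d_short == 1:
        return w_short
    if d_long == 1 and d_short == 1:
        return w_diag
    return 0.0


def build_incidence(
    layout: FieldLayout,
    clone_index: dict,
    func: CompetitionFunction,
    ii_func: CompetitionFunction | None = None,
) -> IncidenceSet:
    """Build Z1, Z2 and II for a layout.

    ``clone_index`` maps clone ID to genotype column.  ``func`` drives
    both Z2 and II unless ``ii_func`` overrides the plot-level (II)
    weight rule, as when genotypic competition and competition error
    follow different decay patterns.
    """
    n = layout.n_plots
    g = len(clone_index)
    cols = np.empty(n, dtype=int)
    for i, clone in enumerate(layout.clone_ids):
        try:
            cols[i] = clone_index[clone]
        except KeyError:
            raise KeyError(f"clone {clone!r} missing from the clone index") from None
    Z1 = np.zeros((n, g))
    Z1[np.arange(n), cols] = 1.0
    W = func.weights(layout)
    Z2 = W @ Z1
    II = W if ii_func is None else ii_func.weights(layout)
    return IncidenceSet(Z1=Z1, Z2=Z2, II=II, clone_index=dict(clone_index))


def clone_index_from_layout(layout: FieldLayout) -> dict:
    """Stable clone -> column map (first-appearance order)."""
    index: dict = {}
    for clone in layout.clone_ids:
        if clone not in index:
            index[clone] = len(index)
    return index
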