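"""Two-sample comparison in a 2-D feature space via local Fisher's exact tests.

Two sequence sets are projected to per-sequence (x, y) points by two scalar
features.  The feature space is divided into a square grid of cells; a window
of size (range_x/k1, range_y/k2) is centered at each cell of the
(k1·l1) × (k2·l2) cell grid (step range/(k·l), i.e. windows overlap by the
factors l1, l2).  For every window a 2×2 contingency table — set-1/set-2
counts inside vs outside the window — is tested with the two-sided Fisher's
exact test against the null hypothesis that the local composition equals the
global one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .features import Feature
from .seqio import SequenceSet

__all__ = [
    "GridSpec",
    "ContingencyTable",
    "ScanResult",
    "fisher_exact_two_sided",
    "assign_windows",
    "point_fisher_scan",
    "local_fisher_scan",
]

#: Relative tolerance on the "point probability <= observed" comparison that
#: gathers tables into the two-sided p-value.
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table: a/b = set-1/set-2 points inside the window, c/d outside."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value by hypergeometric enumeration.

    Conditional on the margins, the count ``a`` follows a hypergeometric
    distribution; the p-value sums the probabilities of all tables whose
    point probability does not exceed the observed one (relative tolerance
    ``TIE_RTOL`` on the comparison).  Any zero margin gives p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n1, n2, k = a + c, b + d, a + b
    if n1 == 0 or n2 == 0 or k == 0 or c + d == 0:
        return 1.0
    total = n1 + n2
    support = np.arange(max(0, k - n2), min(n1, k) + 1)
    # log C(n1, x) + log C(n2, k-x) - log C(total, k)
    logpmf = (_logcomb(n1, support) + _logcomb(n2, k - support)
              - _logcomb(total, k))
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[np.searchsorted(support, a)]
    include = pmf <= observed * (1.0 + TIE_RTOL)
    if include.all():  # observed table is modal: every table gathered
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def _logcomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the sliding-window grid.

    ``k1, k2`` divide the feature-space ranges into the window size
    (range/k); ``l1, l2`` are the overlap factors setting the step
    (range/(k·l)).  The cell grid has k1·l1 × k2·l2 cells; the window
    belonging to a cell is centered at the cell's center and clipped to the
    bounds at the edges.  ``bounds = (x_min, x_max, y_min, y_max)`` defaults
    to the bounding box of the pooled points.
    """

    k1: int = 5
    k2: int = 5
    l1: int = 5
    l2: int = 5
    bounds: tuple | None = None

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.l1, self.l2) < 1:
            raise ValueError("k1, k2, l1, l2 must be >= 1")
        if self.bounds is not None:
            x_min, x_max, y_min, y_max = self.bounds
            if not (x_max > x_min and y_max > y_min):
                raise ValueError("bounds must satisfy x_max > x_min and "
                                 "y_max > y_min")

    @property
    def shape(self) -> tuple:
        return (self.k1 * self.l1, self.k2 * self.l2)

    def resolve_bounds(self, xs: np.ndarray, ys: np.ndarray) -> tuple:
        if self.bounds is not None:
            return tuple(map(float, self.bounds))
        if xs.size == 0:
            return (0.0, 1.0, 0.0, 1.0)
        x_min, x_max = float(xs.min()), float(xs.max())
        y_min, y_max = float(ys.min()), float(ys.max())
        if x_max == x_min:
            x_max = x_min + 1.0
        if y_max == y_min:
            y_max = y_min + 1.0
        return (x_min, x_max, y_min, y_max)


def _axis_edges(lo: float, hi: float, k: int, l: int):
    """Per-cell window [lo_i, hi_i) intervals along one axis, clipped."""
    span = hi - lo
    window = span / k
    step = span / (k * l)
    centers = lo + (np.arange(k * l) + 0.5) * step
    w_lo = np.maximum(centers - window / 2, lo)
    w_hi = np.minimum(centers + window / 2, hi)
    return w_lo, w_hi


def _memberships(coords: np.ndarray, w_lo: np.ndarray, w_hi: np.ndarray,
                 global_hi: float) -> np.ndarray:
    """Boolean (n_cells, n_points): half-open [lo, hi), global max closed."""
    inside = (coords[None, :] >= w_lo[:, None]) & \
             (coords[None, :] < w_hi[:, None])
    at_top = np.isclose(w_hi, global_hi)
    inside[at_top] |= coords[None, :] == global_hi
    return inside


def assign_windows(points1, points2, spec: GridSpec,
                   strict_bounds: bool = False):
    """Per-cell contingency counts for two point clouds.

    Returns ``(count1, count2, n1, n2, bounds)`` where count1/count2 are
    (k1·l1, k2·l2) arrays of in-window points of each set; c and d of each
    cell's :class:`ContingencyTable` follow as n1 - a and n2 - b.  With
    ``strict_bounds`` a point outside explicit bounds raises; otherwise such
    points count only toward the outside margin.
    """
    p1 = np.asarray(points1, dtype=float).reshape(-1, 2)
    p2 = np.asarray(points2, dtype=float).reshape(-1, 2)
    xs = np.concatenate([p1[:, 0], p2[:, 0]])
    ys = np.concatenate([p1[:, 1], p2[:, 1]])
    x_min, x_max, y_min, y_max = spec.resolve_bounds(xs, ys)
    if strict_bounds and xs.size:
        if (xs.min() < x_min or xs.max() > x_max
                or ys.min() < y_min or ys.max() > y_max):
            raise ValueError("point outside the declared bounds")
    xlo, xhi = _axis_edges(x_min, x_max, spec.k1, spec.l1)
    ylo, yhi = _axis_edges(y_min, y_max, spec.k2, spec.l2)

    # (cells_x, points) @ (points, cells_y) -> (cells_x, cells_y)
    def counts(p: np.ndarray) -> np.ndarray:
        if p.shape[0] == 0:
            return np.zeros(spec.shape, dtype=int)
        in_x = _memberships(p[:, 0], xlo, xhi, x_max)
        in_y = _memberships(p[:, 1], ylo, yhi, y_max)
        return in_x.astype(np.int64) @ in_y.T.astype(np.int64)

    return (counts(p1), counts(p2), p1.shape[0], p2.shape[0],
            (x_min, x_max, y_min, y_max))


@dataclass
class ScanResult:
    """Cell-centered grids from a local Fisher scan.

    ``ratio`` holds count1/(count1+count2) with NaN marking empty windows;
    ``pvalues`` the raw two-sided Fisher p-values; ``pvalues_adjusted`` the
    Bonferroni-corrected ones when requested.  Grids are indexed
    [x_cell, y_cell].
    """

    count1: np.ndarray
    count2: np.ndarray
    ratio: np.ndarray
    pvalues: np.ndarray
    global_ratio: float
    bounds: tuple
    spec: GridSpec
    pvalues_adjusted: np.ndarray | None = None

    @property
    def log10_pvalues(self) -> np.ndarray:
        return np.log10(self.pvalues)

    def min_p(self) -> tuple:
        """(min raw p, (x_cell, y_cell)) of the most significant window."""
        idx = np.unravel_index(np.argmin(self.pvalues), self.pvalues.shape)
        return float(self.pvalues[idx]), (int(idx[0]), int(idx[1]))

    def cell_center(self, i: int, j: int) -> tuple:
        x_min, x_max, y_min, y_max = self.bounds
        nx, ny = self.spec.shape
        return (x_min + (i + 0.5) * (x_max - x_min) / nx,
                y_min + (j + 0.5) * (y_max - y_min) / ny)

    def write(self, prefix, sep: str = "\t") -> None:
        """Write count1/count2/ratio/log10 p grids as <prefix>.<name>.tsv."""
        grids = {"count1": self.count1, "count2": self.count2,
                 "ratio": self.ratio, "log10p": self.log10_pvalues}
        for name, grid in grids.items():
            with open(f"{prefix}.{name}.tsv", "w") as handle:
                for row in np.asarray(grid, dtype=float):
                    handle.write(sep.join(format(v, ".6g") for v in row)
                                 + "\n")

    def plot(self, path=None):
        """Render count/ratio/log10-p heat maps (three panels)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        panels = [(self.count1 + self.count2, "counts"),
                  (self.ratio, "set-1 ratio"),
                  (self.log10_pvalues, "log10 p")]
        for ax, (grid, title) in zip(axes, panels):
            im = ax.imshow(np.asarray(grid, dtype=float).T, origin="lower",
                           extent=self.bounds, aspect="auto")
            ax.set_title(title)
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def point_fisher_scan(points1, points2, spec: GridSpec = GridSpec(),
                      bonferroni: bool = False,
                      strict_bounds: bool = False) -> ScanResult:
    """Fisher scan of two pre-computed point clouds."""
    count1, count2, n1, n2, bounds = assign_windows(
        points1, points2, spec, strict_bounds)
    shape = spec.shape
    pvalues = np.ones(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            a, b = int(count1[i, j]), int(count2[i, j])
            pvalues[i, j] = fisher_exact_two_sided(
                ContingencyTable(a, b, n1 - a, n2 - b))
    window_total = count1 + count2
    with np.errstate(invalid="ignore"):
        ratio = np.where(window_total > 0,
                         count1 / np.maximum(window_total, 1), np.nan)
    global_ratio = n1 / (n1 + n2) if n1 + n2 else math.nan
    adjusted = None
    if bonferroni:
        adjusted = np.minimum(pvalues * pvalues.size, 1.0)
    return ScanResult(count1, count2, ratio, pvalues, global_ratio,
                      bounds, spec, adjusted)


def local_fisher_scan(set1: SequenceSet, set2: SequenceSet,
                      feat_x: Feature, feat_y: Feature,
                      spec: GridSpec = GridSpec(),
                      bonferroni: bool = False) -> ScanResult:
    """Fisher scan of two sequence sets under two scalar features."""
    points1 = feature_points(set1, feat_x, feat_y)
    points2 = feature_points(set2, feat_x, feat_y)
    return point_fisher_scan(points1, points2, spec, bonferroni)


def feature_points(sset: SequenceSet, feat_x: Feature,
                   feat_y: Feature) -> np.ndarray:
    """Per-sequence (x, y) coordinates from two scalar features."""
    points = []
    for rec in sset:
        rx, ry = feat_x(rec), feat_y(rec)
        if len(rx) != 1 or len(ry) != 1:
            raise ValueError(
                f"features must be scalar per sequence; record "
                f"{rec.identifier!r} gave lengths {len(rx)}, {len(ry)}")
        points.append((float(rx.data[0]), float(ry.data[0])))
    return np.asarray(points, dtype=float).reshape(-1, 2)
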