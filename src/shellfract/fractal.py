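"""Box counting and Minkowski–Bouligand dimension estimation.

The Minkowski–Bouligand (box-counting) dimension of a binary 3D image is
estimated as the negative slope of an ordinary least-squares regression of
log N(ε) on log ε, where N(ε) is the number of boxes of physical edge
ε = s · voxel_size (s in voxels) containing at least one set voxel. Boxes are
anchored at voxel index (0,0,0) — no offset scanning — with ⌈n/s⌉ boxes per
axis, partial boxes at the high end participating. The standard error of the
dimension is the OLS slope standard error, and the 95% confidence interval is
the slope t-interval.

Two diagnostics accompany the estimate:

* :func:`partition_fit` splits the curve at a physical box-size threshold
  (0.055 cm in the shell study) and fits coarse and fine scale bands
  independently; a rough surface whose ornament lives at a particular scale
  shows different slopes in the two bands.
* :func:`residual_trend` fits a quadratic in log ε to the regression
  residuals; a single power law leaves no trend, while a biphasic curve fitted
  as one line leaves a parabola whose vertex marks the crossover scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .errors import InsufficientScalesError, ParameterError
from .voxelizer import VoxelGrid

__all__ = [
    "BoxCountCurve",
    "FractalFit",
    "ScalePartition",
    "ResidualTrend",
    "dyadic_sizes",
    "box_count",
    "fit_dmb",
    "partition_fit",
    "residual_trend",
]


@dataclass
class BoxCountCurve:
    """(box size, count) pairs for one specimen, sorted by increasing size."""

    sizes_voxels: np.ndarray  # integer box edge s, voxels
    counts: np.ndarray  # N(ε), positive integers
    voxel_size: float  # physical edge of one voxel
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.sizes_voxels = np.asarray(self.sizes_voxels, dtype=np.int64)
        # counts are integers from box_count but stored as float so synthetic
        # curves with exact log-log slopes can be represented losslessly
        self.counts = np.asarray(self.counts, dtype=np.float64)
        order = np.argsort(self.sizes_voxels)
        self.sizes_voxels = self.sizes_voxels[order]
        self.counts = self.counts[order]
        if np.any(self.counts <= 0):
            raise ParameterError("box counts must be positive")
        # monotonicity is only guaranteed between nested tilings (s | s'):
        # anchored boxes of unrelated sizes may split voxels differently
        for i in range(len(self.sizes_voxels) - 1):
            if (
                self.sizes_voxels[i + 1] % self.sizes_voxels[i] == 0
                and self.counts[i + 1] > self.counts[i]
            ):
                raise ParameterError("box counts must be non-increasing for nested box sizes")

    @property
    def sizes_physical(self) -> np.ndarray:
        """ε = s · voxel_size."""
        return self.sizes_voxels * self.voxel_size

    @property
    def entries(self) -> list[tuple[int, float, float]]:
        return [
            (int(s), float(s * self.voxel_size), float(n))
            for s, n in zip(self.sizes_voxels, self.counts)
        ]

    def __len__(self) -> int:
        return int(self.sizes_voxels.size)


@dataclass
class FractalFit:
    """OLS estimate of the box-counting dimension with uncertainty."""

    d_mb: float
    se_d: float
    ci95_low: float
    ci95_high: float
    residuals: np.ndarray  # per fitted entry, log-scale
    fit_sizes_voxels: np.ndarray
    fit_sizes_physical: np.ndarray
    fit_counts: np.ndarray
    r_squared: float

    @property
    def n_scales(self) -> int:
        return int(self.fit_sizes_voxels.size)


@dataclass
class ScalePartition:
    """Independent coarse-/fine-scale fits split at a physical box size."""

    threshold_physical: float
    coarse_fit: FractalFit | None  # ε > threshold
    fine_fit: FractalFit | None  # ε <= threshold (ties join the fine side)


@dataclass
class ResidualTrend:
    """Quadratic trend of fit residuals along log box size."""

    quadratic_coeff: float
    vertex_log_eps: float
    p_value: float


def dyadic_sizes(max_dim: int) -> list[int]:
    """The default box-size series 1, 2, 4, … up to max_dim / 2."""
    sizes = []
    s = 1
    while s <= max_dim // 2:
        sizes.append(s)
        s *= 2
    return sizes


def box_count(grid: VoxelGrid, sizes="dyadic") -> BoxCountCurve:
    """Count occupied boxes of each edge length ``s`` (voxels).

    The grid is tiled by s³-voxel boxes anchored at index (0,0,0); partial
    boxes at the high end count when they contain a set voxel. ``sizes`` is a
    list of integers in [1, max(dims)] or ``"dyadic"`` for 1, 2, 4, … up to
    max(dims)/2.
    """
    occ = grid.occupancy
    if not occ.any():
        raise ParameterError("cannot box-count an empty grid")
    dims = occ.shape
    if isinstance(sizes, str):
        if sizes != "dyadic":
            raise ParameterError(f"unknown size series {sizes!r}")
        size_list = dyadic_sizes(max(dims))
    else:
        size_list = sorted({int(s) for s in sizes})
    counts = []
    for s in size_list:
        if s < 1 or s > max(dims):
            raise ParameterError(f"box size {s} outside [1, {max(dims)}]")
        if s == 1:
            counts.append(int(np.count_nonzero(occ)))
            continue
        nb = [int(np.ceil(d / s)) for d in dims]
        padded = occ
        pad = [(0, nb[a] * s - dims[a]) for a in range(3)]
        if any(p[1] for p in pad):
            padded = np.pad(occ, pad, mode="constant", constant_values=False)
        blocks = padded.reshape(nb[0], s, nb[1], s, nb[2], s)
        counts.append(int(np.count_nonzero(blocks.any(axis=(1, 3, 5)))))
    return BoxCountCurve(
        sizes_voxels=np.asarray(size_list),
        counts=np.asarray(counts),
        voxel_size=grid.voxel_size,
        specimen_id=grid.specimen_id,
    )


def _ols_fit(log_eps: np.ndarray, log_n: np.ndarray) -> tuple:
    X = sm.add_constant(log_eps)
    res = sm.OLS(log_n, X).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    df = len(log_eps) - 2
    tq = float(scipy.stats.t.ppf(0.975, df)) if df > 0 else 0.0
    return slope, se, tq, np.asarray(res.resid), float(res.rsquared)


def fit_dmb(curve: BoxCountCurve, entry_filter=None) -> FractalFit:
    """Estimate D_MB = −slope of OLS(log N(ε) ~ log ε) over selected entries.

    ``entry_filter`` is an optional predicate ``f(size_voxels, eps, count)``
    selecting the entries to fit; at least 3 entries must survive.
    """
    s = curve.sizes_voxels
    eps = curve.sizes_physical
    n = curve.counts
    if entry_filter is not None:
        keep = np.asarray(
            [bool(entry_filter(int(si), float(ei), float(ni))) for si, ei, ni in zip(s, eps, n)]
        )
        s, eps, n = s[keep], eps[keep], n[keep]
    if len(s) < 3:
        raise InsufficientScalesError(
            f"need >= 3 box sizes to fit a dimension, got {len(s)}"
        )
    log_eps = np.log(eps)
    log_n = np.log(n.astype(np.float64))
    if np.ptp(log_eps) == 0.0:
        raise ParameterError("zero variance in log box size")
    slope, se, tq, resid, rsq = _ols_fit(log_eps, log_n)
    d = -slope
    return FractalFit(
        d_mb=d,
        se_d=se,
        ci95_low=d - tq * se,
        ci95_high=d + tq * se,
        residuals=resid,
        fit_sizes_voxels=s.copy(),
        fit_sizes_physical=eps.copy(),
        fit_counts=n.copy(),
        r_squared=rsq,
    )


def partition_fit(curve: BoxCountCurve, threshold_physical: float) -> ScalePartition:
    """Fit coarse (ε > threshold) and fine (ε ≤ threshold) bands independently.

    The threshold must lie strictly inside the curve's physical size range.
    An entry exactly at the threshold joins the fine side. A side with fewer
    than 3 entries is marked absent (``None``) rather than fitted; at least
    one side must be fittable.
    """
    eps = curve.sizes_physical
    if not (eps.min() < threshold_physical < eps.max()):
        raise ParameterError(
            f"threshold {threshold_physical} outside physical size range "
            f"({eps.min():.6g}, {eps.max():.6g})"
        )
    coarse_keep = eps > threshold_physical
    fine_keep = ~coarse_keep
    if coarse_keep.sum() < 3 and fine_keep.sum() < 3:
        raise ParameterError("neither side of the threshold has >= 3 entries")

    def _side(keep: np.ndarray) -> FractalFit | None:
        if keep.sum() < 3:
            return None
        sub = BoxCountCurve(
            sizes_voxels=curve.sizes_voxels[keep],
            counts=curve.counts[keep],
            voxel_size=curve.voxel_size,
            specimen_id=curve.specimen_id,
        )
        return fit_dmb(sub)

    return ScalePartition(
        threshold_physical=float(threshold_physical),
        coarse_fit=_side(coarse_keep),
        fine_fit=_side(fine_keep),
    )


def residual_trend(fit: FractalFit) -> ResidualTrend:
    """OLS of fit residuals on (log ε, (log ε)²).

    Returns the quadratic coefficient with its t-test p-value and the parabola
    vertex −b/(2a) in log ε. Needs at least 4 residuals (one more than the
    quadratic's parameters).
    """
    if fit.residuals.size < 4:
        raise InsufficientScalesError(
            f"need >= 4 residuals for a quadratic trend, got {fit.residuals.size}"
        )
    x = np.log(fit.fit_sizes_physical)
    X = np.column_stack([np.ones_like(x), x, x * x])
    res = sm.OLS(fit.residuals, X).fit()
    a = float(res.params[2])
    b = float(res.params[1])
    p = float(res.pvalues[2])
    if not np.isfinite(p):  # zero residual variance: no evidence of curvature
        p = 1.0
    vertex = -b / (2.0 * a) if a != 0.0 else float("nan")
    return ResidualTrend(quadratic_coeff=a, vertex_log_eps=vertex, p_value=min(max(p, 0.0), 1.0))
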