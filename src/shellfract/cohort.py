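"""Population-level statistics over per-specimen fractal results.

Works on tidy tables (pandas) of one row per specimen: the box-counting
dimension ``d_mb`` and its standard error ``se_d``, a subjective first-order
sculpture category (W = weak, I = intermediate, S = strong), the lake basin
(N / S / other) and optional linear measurements. The statistics mirror a
standard morphometric cohort work-up: fixed-bandwidth Gaussian kernel
densities of the dimension and its error, a one-way ANOVA with Tukey HSD
pairwise comparisons across sculpture categories, a normal-theory z test of a
focal specimen against the rest of the cohort, and min/max/mean/range summary
tables per category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateCohortError, ParameterError

__all__ = [
    "CohortRecord",
    "DensityCurve",
    "GroupComparison",
    "kde_density",
    "group_compare",
    "outlier_vs_cohort",
    "summarize_by_group",
    "records_to_frame",
    "linear_ratios",
]

SCULPTURE_CATEGORIES = ("W", "I", "S")
BASIN_CATEGORIES = ("N", "S", "other")


@dataclass
class CohortRecord:
    """One specimen's fractal result plus metadata."""

    specimen_id: str
    d_mb: float
    se_d: float
    sculpture: str | None = None
    basin: str | None = None
    height: float | None = None
    width: float | None = None
    ratios: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sculpture is not None and self.sculpture not in SCULPTURE_CATEGORIES:
            raise ParameterError(
                f"sculpture category {self.sculpture!r} not in {SCULPTURE_CATEGORIES}"
            )
        if self.basin is not None and self.basin not in BASIN_CATEGORIES:
            raise ParameterError(f"basin {self.basin!r} not in {BASIN_CATEGORIES}")
        for name, value in self.ratios.items():
            if not value > 0:
                raise ParameterError(f"ratio {name!r} must be > 0, got {value}")


def records_to_frame(records) -> pd.DataFrame:
    """Normalise a list of CohortRecord / dicts or a DataFrame to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if isinstance(r, CohortRecord):
            row = {
                "specimen_id": r.specimen_id,
                "d_mb": r.d_mb,
                "se_d": r.se_d,
                "sculpture": r.sculpture,
                "basin": r.basin,
                "height": r.height,
                "width": r.width,
            }
            row.update(r.ratios)
        else:
            row = dict(r)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class DensityCurve:
    """A fixed-bandwidth Gaussian KDE, normalised to unit trapezoid integral."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def kde_density(values, bandwidth: float = 0.02, n_grid: int = 513) -> DensityCurve:
    """Gaussian kernel density with an absolute bandwidth (default 0.02,
    in the units of ``values`` — D_MB units for dimension densities).

    The evaluation grid spans the data range ± 3 bandwidths; the curve is
    explicitly renormalised so its trapezoid integral is 1.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ParameterError("kde_density needs >= 1 finite value")
    if not bandwidth > 0:
        raise ParameterError(f"bandwidth must be > 0, got {bandwidth}")
    grid = np.linspace(v.min() - 3 * bandwidth, v.max() + 3 * bandwidth, n_grid)
    z = (grid[:, None] - v[None, :]) / bandwidth
    density = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bandwidth * np.sqrt(2 * np.pi))
    density /= np.trapezoid(density, grid)
    return DensityCurve(grid=grid, density=density, bandwidth=float(bandwidth))


@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise adjusted p-values."""

    f_statistic: float
    p_value: float
    pairwise: list  # (group_a, group_b, tukey_p)
    groups: list


def group_compare(
    records,
    value_field: str = "d_mb",
    group_field: str = "sculpture",
    pairwise: bool = True,
) -> GroupComparison:
    """One-way ANOVA of ``value_field`` across ``group_field`` levels,
    with Tukey's HSD (studentized-range) adjusted p for every unordered pair.
    ``pairwise=False`` skips the Tukey step (useful in calibration loops that
    only consume the ANOVA p-value).
    """
    df = records_to_frame(records).dropna(subset=[value_field, group_field])
    names, samples = [], []
    for name, sub in df.groupby(group_field, sort=True):
        if len(sub) < 2:
            raise ParameterError(f"group {name!r} has fewer than 2 records")
        names.append(name)
        samples.append(sub[value_field].to_numpy(dtype=np.float64))
    if len(names) < 2:
        raise ParameterError("group_compare needs >= 2 groups")
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
        # all values identical: no variance at all, trivially indistinguishable
        f_stat, p = 0.0, 1.0
        pairwise = [(a, b, 1.0) for i, a in enumerate(names) for b in names[i + 1:]]
        return GroupComparison(f_stat, p, pairwise, names)
    f_stat, p = scipy.stats.f_oneway(*samples)
    if not np.isfinite(f_stat):  # zero within-group variance
        f_stat, p = float("inf"), 0.0
    pairs = []
    if pairwise:
        tukey = scipy.stats.tukey_hsd(*samples)
        pairs = [
            (names[i], names[j], float(tukey.pvalue[i, j]))
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    return GroupComparison(float(f_stat), float(p), pairs, names)


def outlier_vs_cohort(value: float, cohort_values) -> float:
    """Two-sided normal-tail p for a focal value against a reference cohort.

    ``cohort_values`` must exclude the focal specimen and contain >= 3 values;
    z = (value − mean) / sd (sd with n−1 denominator).
    """
    v = np.asarray(cohort_values, dtype=np.float64).ravel()
    if v.size < 3:
        raise ParameterError(f"cohort must have >= 3 values, got {v.size}")
    if not np.isfinite(value):
        raise ParameterError("focal value must be finite")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateCohortError("cohort standard deviation is zero")
    z = (value - v.mean()) / sd
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def summarize_by_group(records, value_field: str = "d_mb", group_field: str = "sculpture") -> pd.DataFrame:
    """Min/max/mean/range of ``value_field`` per group plus an ``all`` row."""
    df = records_to_frame(records).dropna(subset=[value_field])
    rows = []
    grouped = df.dropna(subset=[group_field]).groupby(group_field, sort=True)
    for name, sub in grouped:
        v = sub[value_field].to_numpy(dtype=np.float64)
        rows.append(
            {
                "group": name,
                "n": v.size,
                "min": v.min(),
                "max": v.max(),
                "mean": v.mean(),
                "range": v.max() - v.min(),
            }
        )
    v = df[value_field].to_numpy(dtype=np.float64)
    rows.append(
        {"group": "all", "n": v.size, "min": v.min(), "max": v.max(),
         "mean": v.mean(), "range": v.max() - v.min()}
    )
    return pd.DataFrame(rows)


def linear_ratios(
    height: float,
    width: float,
    aperture_height: float | None = None,
    aperture_width: float | None = None,
    spire_height: float | None = None,
) -> dict:
    """Standard linear shell ratios from caller-supplied measurements."""
    if not (height > 0 and width > 0):
        raise ParameterError("height and width must be > 0")
    out = {"height_width": height / width}
    if aperture_height is not None and aperture_width is not None:
        out["aperture_height_width"] = aperture_height / aperture_width
    if spire_height is not None:
        out["spire_height_shell_height"] = spire_height / height
    if aperture_height is not None:
        out["aperture_height_shell_height"] = aperture_height / height
    return out
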