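"""2D fixed-landmark geometric morphometrics.

Shells are landmarked with 49 homologous 2D points per specimen; three named
subsets of those points are analysed separately: ``overall_shape`` (13 points
describing proportions), ``sculpture`` (10 points on the spiral keels), and
``full_set`` (34 points). Generalized Procrustes analysis (GPA) removes
translation, scale and rotation (reflections disallowed, as is standard for
biological shapes); the aligned coordinates are the Procrustes shape
variables analysed by covariance PCA and by a permutation Procrustes ANOVA
(Goodall-style F on Euclidean distances in shape space). Families of p-values
are adjusted with the Benjamini–Hochberg step-up (FDR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateConfigurationError, ParameterError

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSubset",
    "SUBSETS",
    "ProcrustesResult",
    "ShapePCA",
    "select_subset",
    "gpa",
    "pca_shapes",
    "procrustes_anova",
    "adjust_fdr",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_points_file",
    "write_points_file",
]


@dataclass
class LandmarkConfiguration:
    """Ordered 2D landmark coordinates for one specimen."""

    specimen_id: str
    coords: np.ndarray  # (k, 2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"landmarks for {self.specimen_id!r} contain NaN/Inf")

    @property
    def k(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class LandmarkSubset:
    """A named selection of landmarks, 1-based indices."""

    name: str
    indices: tuple


# The three standard shell subsets (1-based landmark numbers).
SUBSETS: dict[str, LandmarkSubset] = {
    "overall_shape": LandmarkSubset(
        "overall_shape", (8, 14, 20, 22, 23, 24, 26, 32, 38, 46, 47, 48, 49)
    ),
    "sculpture": LandmarkSubset("sculpture", (1, 2, 3, 10, 11, 35, 36, 42, 43, 44)),
    "full_set": LandmarkSubset(
        "full_set",
        (1, 2, 3, 4, 5, 6, 7, 8, 10, 11, 12, 13, 14, 20, 22, 23, 24, 26, 32, 33,
         34, 35, 36, 38, 39, 40, 41, 42, 43, 44, 46, 47, 48, 49),
    ),
}


def select_subset(
    config: LandmarkConfiguration, subset: LandmarkSubset | str
) -> LandmarkConfiguration:
    """Filter a configuration down to a named subset (1-based indices)."""
    if isinstance(subset, str):
        if subset not in SUBSETS:
            raise ParameterError(f"unknown subset {subset!r}; choose from {sorted(SUBSETS)}")
        subset = SUBSETS[subset]
    for idx in subset.indices:
        if idx < 1 or idx > config.k:
            raise ParameterError(
                f"subset {subset.name!r} index {idx} out of range for k={config.k}"
            )
    rows = [i - 1 for i in subset.indices]
    return LandmarkConfiguration(config.specimen_id, config.coords[rows])


@dataclass
class ProcrustesResult:
    """GPA output: aligned configurations in shape space."""

    aligned: np.ndarray  # (n, k, 2), centred, unit centroid size, rotated
    mean_shape: np.ndarray  # (k, 2), the arithmetic mean of `aligned`
    centroid_sizes: np.ndarray  # original centroid sizes per specimen
    distances_to_mean: np.ndarray  # root sum of squared differences to mean
    specimen_ids: list
    n_iterations: int


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimising ||source @ R − target||."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes analysis of >= 2 equal-k 2D configurations.

    Iteratively: centre each configuration, scale to unit centroid size,
    rotate each to the current consensus (optimal rotation by SVD of the
    cross-covariance, reflections disallowed), re-estimate the consensus, and
    repeat until the consensus moves less than ``tol`` or 100 iterations.
    The Procrustes distance reported per specimen is the root sum of squared
    coordinate differences to the final mean shape.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ParameterError("gpa needs >= 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ParameterError(f"inconsistent landmark counts: {sorted(ks)}")
    k = ks.pop()
    if k < 3:
        raise DegenerateConfigurationError(f"gpa needs k >= 3 landmarks, got {k}")

    x = np.stack([c.coords for c in configs])  # (n, k, 2)
    x = x - x.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    for c, s in zip(configs, sizes):
        if s == 0:
            raise DegenerateConfigurationError(
                f"configuration {c.specimen_id!r} has zero centroid size"
            )
    x = x / sizes[:, None, None]
    for c, xi in zip(configs, x):
        sv = np.linalg.svd(xi, compute_uv=False)
        if sv[1] < 1e-12 * sv[0]:
            raise DegenerateConfigurationError(
                f"configuration {c.specimen_id!r} is collinear"
            )

    ref = x[0] / np.linalg.norm(x[0])
    aligned = x.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(x.shape[0]):
            aligned[i] = x[i] @ _optimal_rotation(x[i], ref)
        mean = aligned.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        new_ref = mean / np.linalg.norm(mean)
        if np.linalg.norm(new_ref - ref) < tol:
            ref = new_ref
            break
        ref = new_ref
    for i in range(x.shape[0]):
        aligned[i] = x[i] @ _optimal_rotation(x[i], ref)
    mean_shape = aligned.mean(axis=0)
    distances = np.sqrt(((aligned - mean_shape) ** 2).sum(axis=(1, 2)))
    return ProcrustesResult(
        aligned=aligned,
        mean_shape=mean_shape,
        centroid_sizes=sizes,
        distances_to_mean=distances,
        specimen_ids=[c.specimen_id for c in configs],
        n_iterations=n_iter,
    )


@dataclass
class ShapePCA:
    """Covariance PCA of the flattened aligned coordinates."""

    scores: np.ndarray  # (n, c)
    loadings: np.ndarray  # (c, 2k)
    variance_fractions: np.ndarray  # per component, sums to 1


def pca_shapes(result: ProcrustesResult) -> ShapePCA:
    """PCA of the Procrustes shape variables (>= 3 specimens)."""
    n = result.aligned.shape[0]
    if n < 3:
        raise ParameterError(f"pca_shapes needs >= 3 specimens, got {n}")
    y = result.aligned.reshape(n, -1)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    fractions = eig / total if total > 0 else np.zeros_like(eig)
    return ShapePCA(scores=u * s, loadings=vt, variance_fractions=fractions)


def procrustes_anova(
    result: ProcrustesResult,
    group_labels,
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation Procrustes ANOVA on Euclidean distances in shape space.

    F is the ratio of between- to within-group mean squared Euclidean
    distance of the aligned coordinates (Goodall-style); the p-value is
    ``(1 + #{permuted F >= observed F}) / (1 + n_permutations)`` with group
    labels permuted under a seeded generator, so p is never exactly 0.
    """
    labels = np.asarray(group_labels)
    x = result.aligned.reshape(result.aligned.shape[0], -1)
    n = x.shape[0]
    if labels.shape[0] != n:
        raise ParameterError("group_labels length must match specimen count")
    names, codes = np.unique(labels, return_inverse=True)
    g = names.size
    if g < 2:
        raise ParameterError("procrustes_anova needs >= 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ParameterError("every group needs >= 2 specimens")

    t = x - x.mean(axis=0)
    sst = float((t**2).sum())
    # aligned coordinates are O(1) (unit centroid size); variation at the
    # level of alignment round-off means the shapes are identical
    if sst <= n * 1e-20:
        return 0.0, 1.0

    def f_stat(code_vec: np.ndarray) -> float:
        ssb = 0.0
        for gi in range(g):
            sg = t[code_vec == gi].sum(axis=0)
            ssb += float((sg**2).sum()) / counts[gi]
        ssw = sst - ssb
        if ssw <= 0.0:
            return np.inf
        return (ssb / (g - 1)) / (ssw / (n - g))

    f_obs = f_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_permutations, 4_000_000 // max(n * x.shape[1] // 64, 1), 5000))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        # permuting labels == permuting rows of t with labels fixed
        idx = np.argsort(rng.random((b, n)), axis=1)
        ssb = np.zeros(b)
        start = 0
        for gi in range(g):
            rows = idx[:, start:start + counts[gi]]  # (b, n_g) row picks
            sg = t[rows].sum(axis=1)  # (b, p)
            ssb += (sg**2).sum(axis=1) / counts[gi]
            start += counts[gi]
        ssw = sst - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = np.where(ssw > 0, (ssb / (g - 1)) / (ssw / (n - g)), np.inf)
        exceed += int(np.count_nonzero(f_perm >= f_obs - 1e-12))
        done += b
    p = (1 + exceed) / (1 + n_permutations)
    return float(f_obs), float(p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment.

    Sort ascending, scale p_(i) by m/i, take the cumulative minimum from the
    largest rank downwards, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Landmark I/O


def read_landmark_csv(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a combined CSV with columns specimen_id, landmark_index, x, y."""
    df = pd.read_csv(path)
    required = {"specimen_id", "landmark_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    configs = []
    for sid, sub in df.groupby("specimen_id", sort=True):
        sub = sub.sort_values("landmark_index")
        configs.append(LandmarkConfiguration(str(sid), sub[["x", "y"]].to_numpy()))
    return configs


def write_landmark_csv(configs, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for c in configs:
        for i, (x, y) in enumerate(c.coords, start=1):
            rows.append({"specimen_id": c.specimen_id, "landmark_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_points_file(path: str | Path) -> LandmarkConfiguration:
    """Read a per-specimen point list: header ``# id=<id> k=<k>``, then x y lines."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ParameterError(f"{path}: missing '# id=<id> k=<k>' header")
    header = dict(
        item.split("=", 1) for item in lines[0].lstrip("# ").split() if "=" in item
    )
    if "id" not in header or "k" not in header:
        raise ParameterError(f"{path}: header must contain id= and k=")
    k = int(header["k"])
    coords = [tuple(map(float, ln.split()[:2])) for ln in lines[1:]]
    if len(coords) != k:
        raise ParameterError(f"{path}: header promises k={k} but {len(coords)} points found")
    return LandmarkConfiguration(header["id"], np.asarray(coords))


def write_points_file(config: LandmarkConfiguration, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# id={config.specimen_id} k={config.k}"]
    lines += [f"{x:.10g} {y:.10g}" for x, y in config.coords]
    path.write_text("\n".join(lines) + "\n")
    return path
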