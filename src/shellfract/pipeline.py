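"""End-to-end orchestration: STL directory → fractal table → cohort report,
and landmark CSV → shape report.

Configuration lives in a :class:`PipelineConfig`; values can come from a YAML
file, with keyword/CLI overrides taking precedence over the file and the file
over the built-in defaults (500³ voxel resolution, 0.055 cm scale-partition
threshold, 0.02 KDE bandwidth, 100,000 permutations). All randomness flows
from the single top-level ``seed``, fanned out deterministically per stage,
and every run's report embeds the full effective configuration, so a run can
be replayed from its own log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import fractal, landmarks as lm, voxelizer
from .errors import ParameterError, ShellfractError
from .mesh_io import read_stl

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "run_fractal_pipeline",
    "run_landmark_pipeline",
]

logger = logging.getLogger("shellfract")

FRACTAL_COLUMNS = [
    "specimen_id", "d_mb", "se_d", "ci95_low", "ci95_high", "r_squared",
    "d_mb_coarse", "se_d_coarse", "d_mb_fine", "se_d_fine",
    "quad_coeff", "quad_vertex_log_eps", "quad_p", "n_scales",
]


@dataclass
class PipelineConfig:
    """Effective configuration of a pipeline run."""

    stl_paths: list = field(default_factory=list)
    metadata_csv: str | None = None
    landmark_csv: str | None = None
    resolution: int = 500
    padding_voxels: int = 1
    sizes: object = "dyadic"
    threshold_cm: float = 0.055
    kde_bandwidth: float = 0.02
    permutations: int = 100_000
    subset: str = "full_set"
    group_field: str = "basin"
    seed: int = 0
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Build a config with precedence overrides > file > defaults."""
        values = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            unknown = set(loaded) - set(cls.__dataclass_fields__)
            if unknown:
                raise ParameterError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stl_paths"] = [str(p) for p in d["stl_paths"]]
        return d


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed (< 2**31) from the top seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _fit_one(grid, config: PipelineConfig) -> dict:
    curve = fractal.box_count(grid, sizes=config.sizes)
    fit = fractal.fit_dmb(curve)
    row = {
        "specimen_id": grid.specimen_id,
        "d_mb": fit.d_mb,
        "se_d": fit.se_d,
        "ci95_low": fit.ci95_low,
        "ci95_high": fit.ci95_high,
        "r_squared": fit.r_squared,
        "d_mb_coarse": np.nan,
        "se_d_coarse": np.nan,
        "d_mb_fine": np.nan,
        "se_d_fine": np.nan,
        "quad_coeff": np.nan,
        "quad_vertex_log_eps": np.nan,
        "quad_p": np.nan,
        "n_scales": fit.n_scales,
    }
    eps = curve.sizes_physical
    if eps.min() < config.threshold_cm < eps.max():
        part = fractal.partition_fit(curve, config.threshold_cm)
        if part.coarse_fit is not None:
            row["d_mb_coarse"] = part.coarse_fit.d_mb
            row["se_d_coarse"] = part.coarse_fit.se_d
        if part.fine_fit is not None:
            row["d_mb_fine"] = part.fine_fit.d_mb
            row["se_d_fine"] = part.fine_fit.se_d
    if fit.residuals.size >= 4:
        trend = fractal.residual_trend(fit)
        row["quad_coeff"] = trend.quadratic_coeff
        row["quad_vertex_log_eps"] = trend.vertex_log_eps
        row["quad_p"] = trend.p_value
    return row


def run_fractal_pipeline(
    config: PipelineConfig, meshes=None
) -> tuple[pd.DataFrame, dict]:
    """Voxelize and box-count every input shell; assemble the cohort report.

    ``meshes`` may supply in-memory TriangleMesh objects instead of (or in
    addition to) ``config.stl_paths``. Unreadable files are logged and
    skipped; zero successes is an error. Deterministic for a fixed config.
    """
    logger.info("fractal pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))
    inputs = []
    failures = []
    for path in config.stl_paths:
        try:
            inputs.append(read_stl(path))
        except (ShellfractError, OSError) as exc:
            logger.error("skipping %s: %s", path, exc)
            failures.append({"path": str(path), "error": str(exc)})
    if meshes:
        inputs.extend(meshes)

    rows = []
    for mesh in inputs:
        try:
            logger.info(
                "voxelizing %s at %d^3 (padding %d)",
                mesh.id, config.resolution, config.padding_voxels,
            )
            grid = voxelizer.voxelize_surface(
                mesh, resolution=config.resolution, padding_voxels=config.padding_voxels
            )
            rows.append(_fit_one(grid, config))
        except ShellfractError as exc:
            logger.error("skipping %s: %s", mesh.id, exc)
            failures.append({"path": mesh.id, "error": str(exc)})
    if not rows:
        raise ShellfractError("fractal pipeline produced zero successful specimens")
    table = pd.DataFrame(rows, columns=FRACTAL_COLUMNS)

    report: dict = {"config": config.to_dict(), "failures": failures}
    report["summary_all"] = cohort_mod.summarize_by_group(
        table.assign(sculpture=None), "d_mb", "sculpture"
    ).to_dict("records")

    if config.metadata_csv is not None:
        meta = pd.read_csv(config.metadata_csv)
        merged = table.merge(meta, on="specimen_id", how="left")
        report.update(_cohort_report(merged, config))
        table = merged
    return table, report


def _density_payload(values, bandwidth: float) -> dict:
    d = cohort_mod.kde_density(values, bandwidth=bandwidth)
    return {
        "grid": d.grid.tolist(),
        "density": d.density.tolist(),
        "bandwidth": d.bandwidth,
    }


def _cohort_report(merged: pd.DataFrame, config: PipelineConfig) -> dict:
    out: dict = {}
    out["densities"] = {
        "d_mb": _density_payload(merged["d_mb"], config.kde_bandwidth),
        "se_d": _density_payload(merged["se_d"], config.kde_bandwidth),
    }
    if "sculpture" in merged.columns and merged["sculpture"].notna().any():
        out["summary_by_sculpture"] = cohort_mod.summarize_by_group(
            merged, "d_mb", "sculpture"
        ).to_dict("records")
        counts = merged.dropna(subset=["sculpture"]).groupby("sculpture").size()
        if len(counts) >= 2 and counts.min() >= 2:
            cmp_ = cohort_mod.group_compare(merged, "d_mb", "sculpture")
            out["sculpture_anova"] = {
                "f_statistic": cmp_.f_statistic,
                "p_value": cmp_.p_value,
                "tukey_pairwise": [
                    {"group_a": a, "group_b": b, "p": p} for a, b, p in cmp_.pairwise
                ],
            }
    # the specimen with the largest slope standard error, tested against the
    # rest of the cohort (the work-up that singles out extreme sculpture)
    if len(merged) >= 4:
        focal_idx = merged["se_d"].idxmax()
        rest = merged.drop(index=focal_idx)
        out["max_se_outlier"] = {
            "specimen_id": str(merged.loc[focal_idx, "specimen_id"]),
            "se_d": float(merged.loc[focal_idx, "se_d"]),
            "p_se": cohort_mod.outlier_vs_cohort(
                float(merged.loc[focal_idx, "se_d"]), rest["se_d"]
            ),
            "p_d_mb": cohort_mod.outlier_vs_cohort(
                float(merged.loc[focal_idx, "d_mb"]), rest["d_mb"]
            ),
        }
    return out


def run_landmark_pipeline(config: PipelineConfig, configs=None, groups=None) -> dict:
    """GPA → subset → PCA → permutation Procrustes ANOVA → FDR report.

    ``configs``/``groups`` may be given in memory; otherwise landmarks come
    from ``config.landmark_csv`` and group labels from ``config.metadata_csv``
    (column ``config.group_field`` matched on specimen_id).
    """
    logger.info("landmark pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))
    if configs is None:
        if config.landmark_csv is None:
            raise ParameterError("no landmark input given")
        configs = lm.read_landmark_csv(config.landmark_csv)
    configs = list(configs)
    ks = pd.Series([c.k for c in configs], index=[c.specimen_id for c in configs])
    if ks.nunique() > 1:
        mode = ks.mode().iloc[0]
        offenders = sorted(ks.index[ks != mode])
        raise ParameterError(
            f"inconsistent landmark count: expected k={mode}, offenders: {offenders}"
        )

    if groups is None and config.metadata_csv is not None:
        meta = pd.read_csv(config.metadata_csv).set_index("specimen_id")
        groups = [meta.loc[c.specimen_id, config.group_field] for c in configs]

    if config.subset != "raw":
        configs = [lm.select_subset(c, config.subset) for c in configs]
    result = lm.gpa(configs)
    pca = lm.pca_shapes(result)
    report: dict = {
        "config": config.to_dict(),
        "n_specimens": len(configs),
        "k": configs[0].k,
        "subset": config.subset,
        "gpa_iterations": result.n_iterations,
        "distances_to_mean": {
            sid: float(d) for sid, d in zip(result.specimen_ids, result.distances_to_mean)
        },
        "pca_variance_fractions": pca.variance_fractions[:10].tolist(),
        "pca_scores_pc1_3": pca.scores[:, :3].tolist(),
    }
    if groups is not None:
        f, p = lm.procrustes_anova(
            result,
            groups,
            n_permutations=config.permutations,
            seed=stage_seed(config.seed, "procrustes_anova"),
        )
        p_adj = lm.adjust_fdr([p])
        report["procrustes_anova"] = {
            "group_field": config.group_field,
            "f_statistic": f,
            "p_value": p,
            "p_adjusted": float(p_adj[0]),
            "n_permutations": config.permutations,
        }
    return report
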