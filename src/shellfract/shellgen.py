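"""Synthetic sculptured shells and landmark cohorts.

The generator is a Raup-style coiling model: a generating circle is swept
along a logarithmic helicospiral, its radius expanding by a fixed factor per
revolution while the centreline drops axially. Sculpture is added as radial
modulation of the tube radius:

* first-order sculpture — a few broad **spiral keels**, ridges at fixed
  angular positions around the tube that run along the whorls;
* second-order sculpture — many fine **spiral lirae** (same construction,
  much higher count and much smaller amplitude) and **growth increments**,
  a radial ripple along the direction of growth.

The ornament waveform is a raised-cosine spike train,
``bump(φ; c) = ((1 + cos cφ)/2)³ − 5/16``, which has zero mean, ``c`` equally
spaced peaks per revolution of the tube and a fixed peak height, so "larger
amplitude" and "more ridges" have well-defined, monotone meanings. Amplitudes
enter as relative modulations of the local tube radius. Physical scale is
chosen so default shells are a few centimetres high, the size range of the
adult viviparid shells this generator emulates, which makes a 0.055 cm
box-size threshold land between keel and lirae wavelengths.

The generator exists to give the pipeline inputs with controllable sculpture
orders; it is not a calibrated viviparid growth model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .landmarks import LandmarkConfiguration
from .mesh_io import TriangleMesh

__all__ = ["ShellParams", "PRESETS", "generate_shell", "generate_landmark_cohort"]

_BUMP_MEAN = 5.0 / 16.0  # mean of ((1+cos)/2)^3 over a period


def _bump(phi: np.ndarray, count: int) -> np.ndarray:
    """Zero-mean raised-cosine spike train with `count` peaks per revolution."""
    if count <= 0:
        return np.zeros_like(phi)
    return ((1.0 + np.cos(count * phi)) / 2.0) ** 3 - _BUMP_MEAN


@dataclass(frozen=True)
class ShellParams:
    """Generative parameters for a synthetic sculptured shell.

    Lengths are cm. ``expansion`` is the per-revolution growth factor of both
    the tube radius and the coiling radius; ``translation`` scales the axial
    drop per revolution. ``keel_amp`` / ``lirae_amp`` / ``increment_amp`` are
    relative modulations of the local tube radius (dimensionless); lirae are
    by definition the higher-frequency ornament, so ``lirae_count`` must
    exceed ``keel_count`` when both are present. ``seed`` only matters when
    ``jitter`` > 0 (random vertex perturbation, off by default).
    """

    whorls: float = 3.0
    expansion: float = 1.45
    translation: float = 0.6
    aperture_radius: float = 0.32
    keel_count: int = 3
    keel_amp: float = 0.06
    lirae_count: int = 120
    lirae_amp: float = 0.004
    increment_freq: float = 60.0
    increment_amp: float = 0.002
    theta_steps: int = 960
    phi_steps: int = 720
    jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.whorls > 0:
            raise ParameterError("whorls must be > 0")
        if not self.expansion > 1:
            raise ParameterError("expansion must be > 1")
        if self.translation < 0 or not self.aperture_radius > 0:
            raise ParameterError("translation must be >= 0 and aperture_radius > 0")
        if self.keel_count < 0 or self.lirae_count < 0:
            raise ParameterError("ornament counts must be >= 0")
        if min(self.keel_amp, self.lirae_amp, self.increment_amp, self.jitter) < 0:
            raise ParameterError("amplitudes must be >= 0")
        if self.keel_count > 0 and self.lirae_count > 0 and self.lirae_count <= self.keel_count:
            raise ParameterError("lirae_count must exceed keel_count (second order is finer)")
        if self.theta_steps < 64 * self.whorls:
            raise ParameterError(f"theta_steps must be >= 64*whorls = {64 * self.whorls:.0f}")
        if self.phi_steps < 32:
            raise ParameterError("phi_steps must be >= 32")
        floor = 1.0 - _BUMP_MEAN * (self.keel_amp + self.lirae_amp) - self.increment_amp
        if floor <= 0.05:
            raise ParameterError("combined ornament amplitudes would collapse the tube")


#: Sculpture-category presets: the categories differ in first-order keel
#: strength; second-order lirae are the same order of magnitude in all three.
PRESETS: dict[str, ShellParams] = {
    "weak": ShellParams(keel_amp=0.015),
    "intermediate": ShellParams(keel_amp=0.06),
    "strong": ShellParams(keel_amp=0.12),
}


def generate_shell(params: ShellParams, specimen_id: str | None = None) -> TriangleMesh:
    """Generate a watertight triangulated shell surface.

    The surface point at sweep angle θ (0 … 2π·whorls) and tube angle φ is

    ``P(θ, φ) = ((r_c + r cos φ) cos θ, (r_c + r cos φ) sin θ, z_c + r sin φ)``

    with coiling radius ``r_c = 1.3 · a · W^{θ/2π}``, axial drop
    ``z_c = −translation · W^{θ/2π}`` and tube radius

    ``r(θ, φ) = a · W^{θ/2π} · [1 + keel_amp·bump(φ; keels)
    + lirae_amp·bump(φ; lirae) + increment_amp·sin(increment_freq·θ)]``

    where ``a`` is ``aperture_radius`` and ``W`` ``expansion``. The quad grid
    is closed around φ and capped with triangle fans at both ends, so every
    edge is shared by exactly two faces. Deterministic for fixed parameters;
    ``seed`` only perturbs vertices when ``jitter`` > 0.
    """
    params.validate()
    p = params
    if specimen_id is None:
        specimen_id = f"shell_k{p.keel_amp:g}_l{p.lirae_amp:g}"

    nt = p.theta_steps + 1  # rings, inclusive of both ends
    npphi = p.phi_steps
    theta = np.linspace(0.0, 2.0 * np.pi * p.whorls, nt)
    phi = (2.0 * np.pi / npphi) * np.arange(npphi)

    growth = p.expansion ** (theta / (2.0 * np.pi))  # (nt,)
    r_c = 1.3 * p.aperture_radius * growth
    z_c = -p.translation * growth

    modulation = (
        1.0
        + p.keel_amp * _bump(phi, p.keel_count)[None, :]
        + p.lirae_amp * _bump(phi, p.lirae_count)[None, :]
        + p.increment_amp * np.sin(p.increment_freq * theta)[:, None]
    )
    r = (p.aperture_radius * growth)[:, None] * modulation  # (nt, nphi)

    radial = r_c[:, None] + r * np.cos(phi)[None, :]
    x = radial * np.cos(theta)[:, None]
    y = radial * np.sin(theta)[:, None]
    z = z_c[:, None] + r * np.sin(phi)[None, :]
    ring_vertices = np.stack([x, y, z], axis=-1).reshape(nt * npphi, 3)

    apex_start = np.array([r_c[0] * np.cos(theta[0]), r_c[0] * np.sin(theta[0]), z_c[0]])
    apex_end = np.array([r_c[-1] * np.cos(theta[-1]), r_c[-1] * np.sin(theta[-1]), z_c[-1]])
    vertices = np.vstack([ring_vertices, apex_start, apex_end])
    i_start, i_end = nt * npphi, nt * npphi + 1

    # quad strip between consecutive rings, periodic in phi
    ti = np.repeat(np.arange(nt - 1), npphi)
    pj = np.tile(np.arange(npphi), nt - 1)
    pj1 = (pj + 1) % npphi
    v00 = ti * npphi + pj
    v01 = ti * npphi + pj1
    v10 = (ti + 1) * npphi + pj
    v11 = (ti + 1) * npphi + pj1
    quads = np.concatenate(
        [np.stack([v00, v10, v11], axis=1), np.stack([v00, v11, v01], axis=1)]
    )
    # end caps: fans from the centreline apex points
    j = np.arange(npphi)
    j1 = (j + 1) % npphi
    cap0 = np.stack([np.full(npphi, i_start), j1, j], axis=1)
    cap1 = np.stack(
        [np.full(npphi, i_end), (nt - 1) * npphi + j, (nt - 1) * npphi + j1], axis=1
    )
    faces = np.vstack([quads, cap0, cap1]).astype(np.int64)

    if p.jitter > 0:
        rng = np.random.default_rng(p.seed)
        vertices = vertices + p.jitter * rng.standard_normal(vertices.shape)

    return TriangleMesh(vertices=vertices, faces=faces, unit="cm", id=specimen_id)


def generate_shell_cohort(
    n_per_category: int = 4,
    seed: int = 0,
    theta_steps: int = 960,
    phi_steps: int = 720,
) -> tuple[list[TriangleMesh], list[dict]]:
    """A small cohort spanning the three sculpture presets.

    Within a category, shells vary in coiling geometry (expansion,
    translation, aperture radius) and in second-order sculpture (lirae
    amplitude and count, drawn from a seeded generator) independently of the
    first-order keels, emulating the decoupling of ornament orders in real
    cohorts. Returns meshes plus metadata dicts (specimen_id, sculpture,
    basin).
    """
    rng = np.random.default_rng(seed)
    meshes, meta = [], []
    for label, preset in (("W", "weak"), ("I", "intermediate"), ("S", "strong")):
        for i in range(n_per_category):
            lirae_amp = float(rng.uniform(0.001, 0.008))
            lirae_count = int(rng.integers(90, 150))
            params = replace(
                PRESETS[preset],
                expansion=float(rng.uniform(1.38, 1.52)),
                translation=float(rng.uniform(0.5, 0.7)),
                aperture_radius=float(rng.uniform(0.29, 0.35)),
                keel_amp=float(PRESETS[preset].keel_amp * rng.uniform(0.8, 1.2)),
                lirae_amp=lirae_amp,
                lirae_count=lirae_count,
                increment_amp=float(rng.uniform(0.001, 0.004)),
                theta_steps=theta_steps,
                phi_steps=phi_steps,
            )
            sid = f"{label}{i + 1:02d}"
            meshes.append(generate_shell(params, specimen_id=sid))
            meta.append(
                {"specimen_id": sid, "sculpture": label,
                 "basin": "N" if rng.random() < 0.5 else "S"}
            )
    return meshes, meta


def generate_landmark_cohort(
    n_per_group: int = 20,
    k: int = 49,
    effect_size: float = 0.0,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> tuple[list[LandmarkConfiguration], list[str]]:
    """Two landmark groups with a plantable shape difference.

    Group ``B`` is the base template displaced along a fixed (k-dependent,
    non-similarity) deformation field scaled by ``effect_size``; every
    specimen then receives isotropic Gaussian landmark noise of sd
    ``noise_sd`` and a random similarity transform (rotation, scale,
    translation), so the Procrustes alignment is genuinely exercised.
    Deterministic per seed.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    if k < 3:
        raise ParameterError("k must be >= 3")
    if not noise_sd > 0:
        raise ParameterError("noise_sd must be > 0")
    if effect_size < 0:
        raise ParameterError("effect_size must be >= 0")

    t = 2.0 * np.pi * np.arange(k) / k
    template = np.stack(
        [(1.0 + 0.3 * np.sin(3 * t) + 0.15 * np.cos(5 * t)) * np.cos(t),
         (1.0 + 0.3 * np.sin(3 * t) + 0.15 * np.cos(5 * t)) * np.sin(t)],
        axis=1,
    )
    deform = np.stack([np.sin(5 * t + 0.7), np.cos(7 * t + 0.3)], axis=1)
    deform -= deform.mean(axis=0)
    deform /= np.linalg.norm(deform)

    rng = np.random.default_rng(seed)
    configs, labels = [], []
    for group, base in (("A", template), ("B", template + effect_size * deform)):
        for i in range(n_per_group):
            coords = base + noise_sd * rng.standard_normal((k, 2))
            angle = rng.uniform(0.0, 2.0 * np.pi)
            scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            rot = np.array(
                [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
            )
            coords = scale * coords @ rot.T + rng.uniform(-5.0, 5.0, size=2)
            configs.append(LandmarkConfiguration(f"{group}{i + 1:03d}", coords))
            labels.append(group)
    return configs, labels
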