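# Methods

This note records the models, conventions and numerical choices behind
`shellfract`, and what the synthetic test bed does and does not establish
about real data.

## Surface voxelization

A triangle mesh with physical units (STL carries none; the caller asserts
one, default cm) is rendered into a cubic binary grid. The grid cube has
`resolution` voxels per side (default 500); its physical edge is set by the
longest bounding-box axis plus an empty border of `padding_voxels` (default
1), i.e. `h = max_extent / (resolution − 2·padding)`, and shorter axes are
centred. One scalar voxel size serves all axes, so box sizes have a single
physical meaning per specimen.

A voxel is set iff its **closed** cell intersects at least one triangle,
decided by the exact 13-axis separating-axis test (box normals, triangle
normal, nine edge cross products). Two conventions make the operation
deterministic on constructed, axis-aligned inputs:

* cells are half-open `[origin + i·h, origin + (i+1)·h)` for indexing, and a
  triangle that only touches a boundary plane (zero extent across it) is
  assigned to the lower-index cell, clamped into the grid at the border. An
  axis-aligned cube inscribed in a 10-cell grid therefore occupies exactly
  10³ − 8³ = 488 cells;
* every separating-axis comparison carries a slack of 1e-9·h, so contacts
  constructed to lie exactly on cell planes survive the floating-point
  division that locates candidate cells. The slack is ~10⁻⁷ voxel widths;
  for meshes in general position it is unobservable (the test suite checks
  the fast path voxel-for-voxel against an independent polygon-clipping
  oracle on random meshes).

The voxelization is **surface**, not solid fill. This is the single most
consequential design choice: the box-counting dimension of a filled volume
trends to 3 regardless of ornament, whereas shell surfaces of realistic
roughness land slightly above 2 — the informative regime. Interior filling,
fractional occupancy and grid-offset scanning are deliberately out of scope.

## Box counting and dimension estimation

For a box edge of `s` voxels, the grid is tiled by s³-voxel boxes anchored at
index (0,0,0), ⌈n/s⌉ per axis, partial boxes at the high end counting when
they contain a set voxel (the default one-voxel padding makes edge effects
immaterial). No offset minimisation is performed: single-anchor counting is
deterministic and cheap; offset scanning would only lower N(ε) by a
specimen-dependent amount and is left as future comparison work.

The default size series is dyadic (1, 2, 4, …, ≤ max(dims)/2). Counts are
guaranteed non-increasing only between *nested* tilings (s dividing s′);
anchored boxes of unrelated sizes may split voxels differently, so the curve
container enforces monotonicity only on nested pairs. For partitioned fits of
256-cell grids the pipeline uses a quarter-octave series
(1, 2, 3, 4, 6, 8, 11, 16, 23, 32, 45, 64, 91, 128) so that both sides of the
0.055 cm threshold retain at least three scales.

`fit_dmb` regresses log N(ε) on log ε by OLS; `D_MB = −slope`, its standard
error is the OLS slope SE, and the 95% interval is the slope t-interval.
This reads the per-shell "standard error" of the original work-up as the
regression slope SE — the natural uncertainty of a box-counting estimate.
At least 3 scales are required; an exact power law yields a degenerate
interval. `partition_fit` splits at a physical threshold (entries exactly at
the threshold join the fine side — stated, arbitrary); a side with fewer
than 3 entries is reported absent rather than fitted. `residual_trend` fits
residuals on (log ε, (log ε)²) and reports the quadratic coefficient, its
t-test p (set to 1 when residuals are identically zero, where the test is
undefined and there is no evidence of curvature) and the parabola vertex
−b/(2a).

## Cohort statistics

Kernel densities use a Gaussian kernel with an **absolute** bandwidth
(default 0.02, in D_MB units), evaluated on a 513-point grid spanning the
data range ± 3 bandwidths and renormalised to unit trapezoid integral.
Group comparison is one-way ANOVA with Tukey HSD (studentized range) for all
pairs; Tukey can be skipped in calibration loops that only consume the ANOVA
p. The focal-specimen test is a two-sided normal-tail z-test against the
cohort excluding the focal specimen (sd with n−1); the original analysis
does not name its test, so this choice is documented and deliberately easy
to swap. Linear ratios (height/width etc.) are computed from caller-supplied
measurements only — no image measurement is performed.

## Landmark workflow

49 fixed 2D landmarks per specimen, with three named subsets
(`overall_shape`: 13, `sculpture`: 10, `full_set`: 34 landmarks, 1-based
indices). GPA centres each configuration, scales to unit centroid size,
rotates each to the running consensus (SVD of the cross-covariance,
reflections disallowed — standard for biological shapes), and iterates until
the consensus moves < 1e-10 (max 100 iterations). The reported mean shape is
the arithmetic mean of the aligned configurations, and Procrustes distance
is the root sum of squared coordinate differences. Configurations that are
collinear (rank < 2) are rejected as unalignable.

Shape PCA is a covariance PCA of the flattened aligned coordinates. When
shape variation is small (the regime where the tangent-space approximation
is linear) at least four eigenvalues vanish — two translations, rotation and
scale having been removed; for widely dispersed shapes the scale direction
picks up curvature variance, which is expected behaviour, not error.

The permutation Procrustes ANOVA uses a Goodall-style F (between/within sums
of squared Euclidean distances of aligned coordinates) with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)` — the +1 convention
means p is never exactly 0, which matters when comparing very small reported
p-values. Permutations are vectorised in chunks under a seeded generator;
identical input and seed give bit-identical p. A cohort whose total shape
variation is at alignment round-off (≤ n·1e-20 on unit-size coordinates) is
reported as F = 0, p = 1. FDR adjustment is Benjamini–Hochberg step-up,
implemented directly from the step-up definition and cross-checked against
statsmodels in the tests; the module adjusts whatever p-value family the
caller provides and does not guess the family.

## Synthetic shell generator

A Raup-style model: generating circle of radius `a·W^{θ/2π}` swept along a
helicospiral with coiling radius `1.3·a·W^{θ/2π}` and axial drop
`−translation·W^{θ/2π}` (`W` = expansion per revolution). Ornament
modulates the tube radius relatively:

```
r(θ, φ) = a·W^{θ/2π} · [1 + keel_amp·bump(φ; keel_count)
          + lirae_amp·bump(φ; lirae_count) + increment_amp·sin(increment_freq·θ)]
```

with `bump(φ; c) = ((1 + cos cφ)/2)³ − 5/16`, a zero-mean raised-cosine
spike train with `c` equally spaced peaks — so "more ridges" and "taller
ridges" have well-defined monotone meanings. Amplitudes are dimensionless
relative modulations of the local tube radius (an amplitude of 0.01 on a
1 cm tube is a ~0.007 cm ridge). The quad grid is closed around φ and capped
by fans at both ends: watertight by construction, deterministic for fixed
parameters (`seed` only drives optional vertex jitter).

Default parameters are chosen once to emulate adult sculptured viviparid
shells: ~3 whorls, expansion 1.45, overall size a few cm (so the 0.055 cm
partition threshold separates keel from lirae wavelengths), 3 keels, 120
lirae (≈ 0.05 cm spacing at the body whorl — inside the fine band), gentle
growth increments, and mesh resolution (960 × 720) sufficient to sample the
finest ornament with ≥ 6 vertices per ridge. The sculpture presets
(`weak`/`intermediate`/`strong`) differ only in first-order keel amplitude
(0.015 / 0.06 / 0.12), mirroring the visual categories such cohorts are
sorted into; the cohort generator additionally varies coiling geometry and
second-order ornament independently of category.

The landmark cohort generator displaces group B along a fixed non-similarity
deformation field, adds isotropic landmark noise, and applies a random
similarity transform per specimen so the alignment is genuinely exercised.

What the generator does *not* emulate: µCT scan noise and reconstruction
artefacts, shell thickness and aperture geometry, suture detail,
ontogenetic allometry, broken or encrusted shells. Passing tests therefore
establish the correctness and calibration of the measurement chain and the
scale-resolved behaviour of the dimension under controlled ornament, not
field performance on real scans.

## Problem sizes and numerical conventions

The test suite and acceptance script run the dissociation experiments at
resolution 256 with the quarter-octave size series (both bands keep ≥ 3
scales), resolution-stability checks at 128 vs 256, oracle-equivalence
checks at resolutions ≤ 32 with ≤ 50-triangle meshes, permutation
calibration at 1,000 null cohorts × 999 permutations, and parametric-ANOVA
calibration at 2,000 null cohorts — sizes chosen as the smallest at which
each property is cleanly expressed. The library default for real data
remains 500³ voxels and 100,000 permutations.

Known limitations: single-anchor box counting makes N(ε) (slightly)
orientation- and phase-dependent at coarse scales; the dimension is only
meaningful over the scale band actually fitted; surface voxelization of a
self-intersecting mesh (overlapping whorls) counts the union surface, which
is intended; and the normal-theory outlier test assumes an approximately
normal cohort, which the density diagnostics are there to check.
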