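"""Box counting and dimension estimation against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from oracles import brute_force_box_count, menger_sponge

from shellfract import (
    BoxCountCurve,
    InsufficientScalesError,
    ParameterError,
    VoxelGrid,
    box_count,
    fit_dmb,
    partition_fit,
    residual_trend,
    voxelize_surface,
)


def make_grid(occ, voxel_size=1.0):
    return VoxelGrid(np.asarray(occ, bool), voxel_size, np.zeros(3))


def test_fully_occupied_counts():
    curve = box_count(make_grid(np.ones((8, 8, 8))), [1, 2, 4, 8])
    np.testing.assert_array_equal(curve.counts, [512, 64, 8, 1])


def test_single_voxel_counts_one_everywhere():
    occ = np.zeros((16, 16, 16), bool)
    occ[3, 7, 11] = True
    curve = box_count(make_grid(occ), [1, 2, 3, 5, 8, 16])
    assert (curve.counts == 1).all()


def test_menger_level3_counts():
    curve = box_count(make_grid(menger_sponge(3)), [1, 3, 9, 27])
    np.testing.assert_array_equal(curve.counts, [8000, 400, 20, 1])


def test_box_count_errors():
    with pytest.raises(ParameterError):
        box_count(make_grid(np.zeros((8, 8, 8))), [1, 2])
    with pytest.raises(ParameterError):
        box_count(make_grid(np.ones((8, 8, 8))), [0, 2])
    with pytest.raises(ParameterError):
        box_count(make_grid(np.ones((8, 8, 8))), [9])


@pytest.mark.parametrize("seed,n,fill", [(0, 8, 0.1), (1, 16, 0.02), (2, 16, 0.5), (3, 32, 0.005)])
def test_box_count_matches_brute_force(seed, n, fill):
    """Reshaping-based counting equals exhaustive per-box scanning, all sizes."""
    rng = np.random.default_rng(seed)
    occ = rng.random((n, n, n)) < fill
    if not occ.any():
        occ[0, 0, 0] = True
    curve = box_count(make_grid(occ), list(range(1, n + 1)))
    expected = [brute_force_box_count(occ, s) for s in range(1, n + 1)]
    np.testing.assert_array_equal(curve.counts, expected)


def test_exact_power_law_fit():
    """N = (64/s)^2 gives d = 2 with a degenerate confidence interval."""
    s = np.array([1, 2, 4, 8, 16])
    curve = BoxCountCurve(s, (64 // s) ** 2, voxel_size=0.01)
    fit = fit_dmb(curve)
    assert fit.d_mb == pytest.approx(2.0, abs=1e-12)
    assert fit.se_d == pytest.approx(0.0, abs=1e-9)
    assert fit.ci95_low == pytest.approx(2.0, abs=1e-8)
    assert fit.ci95_high == pytest.approx(2.0, abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0)


def test_fully_occupied_dimension_is_three():
    curve = box_count(make_grid(np.ones((64, 64, 64))), "dyadic")
    assert fit_dmb(curve).d_mb == pytest.approx(3.0, abs=1e-9)


def test_menger_dimension_matches_self_similarity():
    curve = box_count(make_grid(menger_sponge(3)), [1, 3, 9, 27])
    fit = fit_dmb(curve)
    assert fit.d_mb == pytest.approx(np.log(20) / np.log(3), abs=1e-9)


def test_plane_dimension_is_two():
    occ = np.zeros((64, 64, 64), bool)
    occ[:, :, 31] = True
    fit = fit_dmb(box_count(make_grid(occ), "dyadic"))
    assert fit.d_mb == pytest.approx(2.0, abs=0.05)


def test_fit_requires_three_scales_and_size_variance():
    curve = BoxCountCurve([1, 2], [100, 30], voxel_size=1.0)
    with pytest.raises(InsufficientScalesError):
        fit_dmb(curve)


def _biphasic_curve(break_eps=0.055, voxel_size=0.005):
    """Counts following slope 2.5 below the break and 2.0 above, continuous at it."""
    s = np.array([1, 2, 3, 4, 6, 8, 11, 16, 23, 32, 45, 64])
    eps = s * voxel_size
    log_n = np.where(
        eps < break_eps,
        -2.5 * np.log(eps) + 2.5 * np.log(break_eps),
        -2.0 * np.log(eps) + 2.0 * np.log(break_eps),
    ) + 10.0
    return BoxCountCurve(s, np.exp(log_n), voxel_size=voxel_size, specimen_id="biphasic")


def test_partition_recovers_biphasic_slopes():
    curve = _biphasic_curve()
    part = partition_fit(curve, 0.055)
    assert part.coarse_fit.d_mb == pytest.approx(2.0, abs=1e-9)
    assert part.fine_fit.d_mb == pytest.approx(2.5, abs=1e-9)


def test_partition_of_pure_power_law_is_scale_invariant():
    s = np.array([1, 2, 4, 8, 16, 32, 64])
    curve = BoxCountCurve(s, (128 // s) ** 2, voxel_size=0.01)
    part = partition_fit(curve, 0.07)
    assert part.coarse_fit.d_mb == pytest.approx(part.fine_fit.d_mb, abs=1e-9)


def test_partition_threshold_must_be_interior():
    s = np.array([1, 2, 4, 8, 16, 32, 64])
    curve = BoxCountCurve(s, (128 // s) ** 2, voxel_size=0.01)
    with pytest.raises(ParameterError):
        partition_fit(curve, 0.001)
    with pytest.raises(ParameterError):
        partition_fit(curve, 10.0)


def test_partition_side_with_too_few_entries_is_absent():
    s = np.array([1, 2, 4, 8, 16, 32])
    curve = BoxCountCurve(s, (64 // s) ** 2, voxel_size=0.01)
    part = partition_fit(curve, 0.025)  # only s in {1, 2} on the fine side
    assert part.fine_fit is None
    assert part.coarse_fit is not None


def test_residual_trend_zero_for_exact_power_law():
    s = np.array([1, 2, 4, 8, 16])
    fit = fit_dmb(BoxCountCurve(s, (64 // s) ** 2, voxel_size=0.01))
    trend = residual_trend(fit)
    assert abs(trend.quadratic_coeff) < 1e-12
    assert 0.0 <= trend.p_value <= 1.0


def test_residual_trend_detects_biphasic_break():
    """Fitting a biphasic curve as one line leaves an upward parabola whose
    vertex falls within one octave of the break scale."""
    curve = _biphasic_curve(break_eps=0.055)
    fit = fit_dmb(curve)
    trend = residual_trend(fit)
    assert trend.quadratic_coeff > 0
    assert abs(trend.vertex_log_eps - np.log(0.055)) < np.log(2)


def test_residual_trend_needs_four_residuals():
    s = np.array([1, 2, 4, 8])
    fit4 = fit_dmb(BoxCountCurve(s, (64 // s) ** 2, voxel_size=0.01))
    assert 0.0 <= residual_trend(fit4).p_value <= 1.0
    fit3 = fit_dmb(BoxCountCurve(s[:3], ((64 // s) ** 2)[:3], voxel_size=0.01))
    with pytest.raises(InsufficientScalesError):
        residual_trend(fit3)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_local_slopes_bounded(seed):
    """Between adjacent octaves, 0 <= -local slope <= 3 for any occupancy."""
    rng = np.random.default_rng(seed)
    occ = rng.random((32, 32, 32)) < rng.uniform(0.001, 0.3)
    if not occ.any():
        occ[0, 0, 0] = True
    curve = box_count(make_grid(occ), "dyadic")
    local = -np.diff(np.log(curve.counts.astype(float))) / np.diff(
        np.log(curve.sizes_voxels.astype(float))
    )
    assert np.all(local >= -1e-12)
    assert np.all(local <= 3 + 1e-12)


def test_resolution_stability(small_shell):
    """D_MB of the same shell at two resolutions agrees within 0.1."""
    d = {}
    for res in (128, 256):
        curve = box_count(voxelize_surface(small_shell, resolution=res), "dyadic")
        d[res] = fit_dmb(curve).d_mb
    assert abs(d[128] - d[256]) < 0.1
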