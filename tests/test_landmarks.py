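"""Landmark subsets, GPA, shape PCA, permutation ANOVA and FDR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from shellfract import (
    SUBSETS,
    DegenerateConfigurationError,
    LandmarkConfiguration,
    ParameterError,
    adjust_fdr,
    gpa,
    pca_shapes,
    procrustes_anova,
    select_subset,
)
from shellfract.landmarks import (
    read_landmark_csv,
    read_points_file,
    write_landmark_csv,
    write_points_file,
)


def _config(coords, sid="s"):
    return LandmarkConfiguration(sid, np.asarray(coords, float))


def _random_config(rng, k=12, sid="s"):
    return _config(rng.normal(0, 1, (k, 2)), sid)


def _similarity(coords, angle, scale, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return scale * coords @ rot.T + shift


# ---------------------------------------------------------------- subsets


def test_subset_sizes_match_their_definitions():
    assert len(SUBSETS["overall_shape"].indices) == 13
    assert len(SUBSETS["sculpture"].indices) == 10
    assert len(SUBSETS["full_set"].indices) == 34


def test_select_subset_counts_and_order():
    coords = np.column_stack([np.arange(1, 50, dtype=float), np.zeros(49)])
    full = _config(coords)
    overall = select_subset(full, "overall_shape")
    assert overall.k == 13
    # coordinates carry the original 1-based landmark number in x
    np.testing.assert_array_equal(overall.coords[:, 0], SUBSETS["overall_shape"].indices)
    sculpture = select_subset(full, "sculpture")
    assert sculpture.k == 10
    assert sculpture.coords[0, 0] == 1.0  # first sculpture landmark is number 1


def test_select_subset_index_out_of_range_named():
    small = _config(np.random.default_rng(0).normal(size=(20, 2)))
    # first full_set index beyond k=20 is landmark 22; the error names it
    with pytest.raises(ParameterError, match="22"):
        select_subset(small, "full_set")


# ---------------------------------------------------------------- GPA


def test_identical_configs_have_zero_distance():
    rng = np.random.default_rng(0)
    base = _random_config(rng, sid="a")
    result = gpa([base, _config(base.coords, "b")])
    assert np.all(result.distances_to_mean < 1e-12)


def test_similarity_transformed_copy_aligns_exactly():
    rng = np.random.default_rng(1)
    base = _random_config(rng, sid="a")
    moved = _config(_similarity(base.coords, np.radians(37), 2.5, [4.2, -1.0]), "b")
    result = gpa([base, moved])
    assert np.all(result.distances_to_mean < 1e-8)


def test_gpa_invariants():
    rng = np.random.default_rng(2)
    configs = [_random_config(rng, sid=str(i)) for i in range(8)]
    result = gpa(configs)
    centroids = result.aligned.mean(axis=1)
    assert np.all(np.linalg.norm(centroids, axis=1) < 1e-10)
    sizes = np.sqrt((result.aligned**2).sum(axis=(1, 2)))
    np.testing.assert_allclose(sizes, 1.0, atol=1e-10)
    np.testing.assert_allclose(result.mean_shape, result.aligned.mean(axis=0), atol=1e-12)


def test_gpa_output_invariant_under_common_similarity():
    rng = np.random.default_rng(3)
    configs = [_random_config(rng, sid=str(i)) for i in range(6)]
    transformed = [
        _config(_similarity(c.coords, 1.1, 0.3, [100.0, -50.0]), c.specimen_id)
        for c in configs
    ]
    d0 = gpa(configs).distances_to_mean
    d1 = gpa(transformed).distances_to_mean
    np.testing.assert_allclose(d0, d1, atol=1e-8)


def test_pairwise_distance_matches_rotation_grid_search():
    """GPA distance between two triangles equals a brute-force scan over
    rotation angles (after centring and unit scaling) to 1e-4."""
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.8]])
    b = np.array([[0.0, 0.1], [1.1, 0.0], [0.5, 0.9]])

    def normalise(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    an, bn = normalise(a), normalise(b)
    # ||bn R^T - an||^2 = 2 - 2 (P cos t + Q sin t); scan t on a 1e-5 grid
    p_term = float((bn * an).sum())
    q_term = float((bn[:, 0] * an[:, 1] - bn[:, 1] * an[:, 0]).sum())
    t_grid = np.arange(0, 2 * np.pi, 1e-5)
    best = np.sqrt(np.min(2 - 2 * (p_term * np.cos(t_grid) + q_term * np.sin(t_grid))))
    result = gpa([_config(a, "a"), _config(b, "b")])
    pairwise = np.linalg.norm(result.aligned[0] - result.aligned[1])
    assert pairwise == pytest.approx(best, abs=1e-4)


def test_gpa_degenerate_inputs_rejected():
    rng = np.random.default_rng(4)
    with pytest.raises(ParameterError):
        gpa([_random_config(rng)])
    collinear = _config([[0, 0], [1, 1], [2, 2], [3, 3]], "line")
    with pytest.raises(DegenerateConfigurationError):
        gpa([collinear, _random_config(rng, k=4)])
    with pytest.raises(DegenerateConfigurationError):
        gpa([_config([[0, 0], [1, 0]], "a"), _config([[0, 0], [0, 1]], "b")])


# ---------------------------------------------------------------- PCA


def test_pca_variance_fractions_normalised():
    rng = np.random.default_rng(5)
    result = gpa([_random_config(rng, sid=str(i)) for i in range(10)])
    pca = pca_shapes(result)
    assert np.all(pca.variance_fractions >= -1e-15)
    assert np.all(np.diff(pca.variance_fractions) <= 1e-12)
    assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)


def test_pca_recovers_planted_deformation_axis():
    """Variation along one small deformation axis plus sd-1e-6 noise loads PC1."""
    rng = np.random.default_rng(6)
    k = 10
    base = rng.normal(0, 1, (k, 2))
    axis = rng.normal(0, 1, (k, 2))
    axis -= axis.mean(axis=0)
    configs = [
        _config(base + 0.01 * rng.normal() * axis + 1e-6 * rng.normal(0, 1, (k, 2)), str(i))
        for i in range(20)
    ]
    pca = pca_shapes(gpa(configs))
    assert pca.variance_fractions[0] > 0.99


def test_pca_invariant_under_duplicated_cohort():
    rng = np.random.default_rng(7)
    configs = [_random_config(rng, sid=str(i)) for i in range(6)]
    doubled = configs + [_config(c.coords, c.specimen_id + "b") for c in configs]
    f1 = pca_shapes(gpa(configs)).variance_fractions
    f2 = pca_shapes(gpa(doubled)).variance_fractions
    # component counts differ (min(n, 2k)); the non-trivial spectrum agrees
    np.testing.assert_allclose(f1[:5], f2[:5], atol=1e-10)


def test_pca_has_four_null_directions():
    """GPA removes 2 translations, rotation and scale: >= 4 zero eigenvalues
    (for shape variation small enough that the tangent space is linear)."""
    rng = np.random.default_rng(8)
    k = 7
    base = rng.normal(0, 1, (k, 2))
    configs = [
        _config(base + 1e-5 * rng.normal(0, 1, (k, 2)), str(i)) for i in range(30)
    ]
    fractions = np.sort(pca_shapes(gpa(configs)).variance_fractions)
    assert np.all(fractions[:4] < 1e-10)


# ---------------------------------------------------------------- permutation ANOVA


def test_identical_shapes_give_f_zero_p_one():
    rng = np.random.default_rng(9)
    base = _random_config(rng, sid="a")
    configs = [_config(base.coords, str(i)) for i in range(8)]
    f, p = procrustes_anova(gpa(configs), ["A"] * 4 + ["B"] * 4, 99, seed=0)
    assert f == 0.0
    assert p == 1.0


def test_permutation_p_is_deterministic_and_label_invariant():
    rng = np.random.default_rng(10)
    configs = [_random_config(rng, sid=str(i)) for i in range(12)]
    result = gpa(configs)
    labels = ["A"] * 6 + ["B"] * 6
    f1, p1 = procrustes_anova(result, labels, 999, seed=17)
    f2, p2 = procrustes_anova(result, labels, 999, seed=17)
    assert (f1, p1) == (f2, p2)
    renamed = ["carinate" if l == "A" else "smooth" for l in labels]
    f3, p3 = procrustes_anova(result, renamed, 999, seed=17)
    assert (f3, p3) == (f1, p1)


def test_anova_contract_errors():
    rng = np.random.default_rng(11)
    result = gpa([_random_config(rng, sid=str(i)) for i in range(6)])
    with pytest.raises(ParameterError):
        procrustes_anova(result, ["A"] * 6, 99)
    with pytest.raises(ParameterError):
        procrustes_anova(result, ["A", "B", "A", "A", "A", "A"], 99)


def test_strong_group_difference_detected():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 1, (8, 2))
    shift = rng.normal(0, 1, (8, 2)) * 0.5
    configs = [_config(base + rng.normal(0, 0.01, (8, 2)), f"a{i}") for i in range(6)]
    configs += [_config(base + shift + rng.normal(0, 0.01, (8, 2)), f"b{i}") for i in range(6)]
    _, p = procrustes_anova(gpa(configs), ["A"] * 6 + ["B"] * 6, 999, seed=0)
    # a random permutation reproduces the observed split with prob 2/C(12,6),
    # so a few exceedances are expected even for a huge effect
    assert p < 0.01


# ---------------------------------------------------------------- FDR


def test_fdr_hand_worked_example():
    np.testing.assert_allclose(
        adjust_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
    )


def test_fdr_trivial_cases():
    assert adjust_fdr([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(adjust_fdr([0.2] * 5), [0.2] * 5)
    with pytest.raises(ParameterError):
        adjust_fdr([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_fdr_matches_statsmodels(pvals):
    ours = adjust_fdr(pvals)
    _, theirs, _, _ = multipletests(pvals, method="fdr_bh")
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


# ---------------------------------------------------------------- I/O


def test_landmark_io_roundtrips(tmp_path):
    rng = np.random.default_rng(13)
    configs = [_random_config(rng, k=5, sid=f"s{i}") for i in range(3)]
    csv = write_landmark_csv(configs, tmp_path / "lm.csv")
    back = read_landmark_csv(csv)
    assert [c.specimen_id for c in back] == [c.specimen_id for c in configs]
    for a, b in zip(back, configs):
        np.testing.assert_allclose(a.coords, b.coords)
    pts = write_points_file(configs[0], tmp_path / "s0.txt")
    single = read_points_file(pts)
    assert single.specimen_id == "s0" and single.k == 5
    np.testing.assert_allclose(single.coords, configs[0].coords, atol=1e-9)
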