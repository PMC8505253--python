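"""Voxelwise GLM, smoothness estimation and cluster correction."""

import numpy as np
import pytest
from scipy import stats

from subtyper import (
    DesignError,
    DesignSpec,
    SimConfig,
    cluster_correct,
    estimate_smoothness,
    extract_feature_matrix,
    fit_voxelwise_glm,
    generate_cohort,
    select_high_variance_voxels,
)
from subtyper.simulate import default_regions, make_mask

from conftest import make_manual_cohort

TWO_GROUP = DesignSpec(sex_col=None, age_col=None)


def test_group_t_matches_classical_two_sample_t():
    """One voxel, groups [0,1,2] vs [2,3,4]: pooled t = 2.449, df = 4."""
    cohort = make_manual_cohort(
        np.array([[0.0], [1.0], [2.0], [2.0], [3.0], [4.0]]),
        ["control"] * 3 + ["patient"] * 3,
    )
    res = fit_voxelwise_glm(cohort, TWO_GROUP)
    assert res.df == 4
    assert res.t[0] == pytest.approx(2.449, abs=1e-3)
    # cross-check with scipy's pooled two-sample t
    t_ref = stats.ttest_ind([2, 3, 4], [0, 1, 2], equal_var=True).statistic
    assert res.t[0] == pytest.approx(t_ref, abs=1e-10)


def test_identical_groups_give_zero_t_unit_p():
    cohort = make_manual_cohort(
        np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]]),
        ["control"] * 3 + ["patient"] * 3,
    )
    res = fit_voxelwise_glm(cohort, TWO_GROUP)
    assert res.t[0] == 0.0
    assert res.p[0] == 1.0


def test_glm_matches_closed_form_ols_on_random_designs():
    """t for the group coefficient agrees with the normal-equations formula."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(8, 21)
        v = rng.integers(1, 11)
        groups = ["control"] * (n // 2) + ["patient"] * (n - n // 2)
        cohort = make_manual_cohort(rng.standard_normal((n, v)), groups)
        res = fit_voxelwise_glm(cohort)  # includes sex + centered age
        X = res.design
        Y = cohort.masked_data()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y
        resid = Y - X @ beta
        df = n - X.shape[1]
        se = np.sqrt((resid**2).sum(0) / df * XtX_inv[1, 1])
        np.testing.assert_allclose(res.t, beta[1] / se, atol=1e-8)


def test_subject_order_invariance(small_cohort):
    res = fit_voxelwise_glm(small_cohort)
    perm = np.random.default_rng(1).permutation(small_cohort.n_subjects)
    shuffled = make_manual_cohort(
        small_cohort.masked_data()[perm],
        list(small_cohort.phenotypes["group"].to_numpy()[perm]),
    )
    shuffled.phenotypes["age"] = small_cohort.phenotypes["age"].to_numpy()[perm]
    shuffled.phenotypes["sex"] = small_cohort.phenotypes["sex"].to_numpy()[perm]
    res2 = fit_voxelwise_glm(shuffled)
    np.testing.assert_allclose(res2.t, res.t, atol=1e-10)


def test_rank_deficient_design_names_columns():
    cohort = make_manual_cohort(
        np.random.default_rng(0).standard_normal((8, 3)),
        ["control"] * 4 + ["patient"] * 4,
    )
    cohort.phenotypes["age"] = (cohort.phenotypes["group"] == "patient").astype(float)
    with pytest.raises(DesignError, match="age|group"):
        fit_voxelwise_glm(cohort, DesignSpec(sex_col=None))


def test_white_noise_smoothness_near_one_voxel():
    rng = np.random.default_rng(2)
    mask = np.ones((14, 14, 14), dtype=bool)
    resid = rng.standard_normal((20, mask.sum()))
    fwhm = estimate_smoothness(resid, mask)
    assert np.all(fwhm >= 1.0) and np.all(fwhm <= 1.25)


def test_known_smoothness_recovered_within_20_percent():
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(3)
    mask = np.ones((24, 24, 24), dtype=bool)
    sigma = 3.0 / np.sqrt(8 * np.log(2))
    fields = np.stack([
        gaussian_filter(rng.standard_normal(mask.shape), sigma, mode="wrap")
        for _ in range(12)
    ])
    resid = fields.reshape(12, -1)
    fwhm = estimate_smoothness(resid, mask)
    assert np.all(np.abs(fwhm - 3.0) <= 0.6)


def test_constant_residuals_rejected():
    mask = np.ones((5, 5, 5), dtype=bool)
    with pytest.raises(ValueError, match="constant"):
        estimate_smoothness(np.ones((6, mask.sum())), mask)


def test_subthreshold_map_yields_empty_selection(small_cohort):
    res = fit_voxelwise_glm(small_cohort)
    res.t = np.zeros_like(res.t)  # force everything below threshold
    sel = cluster_correct(res, small_cohort.mask)
    assert sel.n_voxels == 0 and sel.clusters == []


@pytest.fixture(scope="module")
def planted_cube_cohort():
    """Patients uniformly shifted (+1 sd) inside a 5x5x5 cube of the mask."""
    grid = (16, 16, 16)
    mask = make_mask(grid, 0.5)
    cube = np.zeros(grid, dtype=bool)
    cube[6:11, 6:11, 6:11] = True
    cube &= mask
    rng = np.random.default_rng(10)
    n = 100
    data = rng.standard_normal((2 * n,) + grid)
    data[:n][:, cube] += 1.0
    flat = data.reshape(2 * n, -1)[:, mask.ravel()]
    cohort = make_manual_cohort(np.zeros((2 * n, 1)), ["patient"] * n + ["control"] * n)
    cohort.volumes = np.zeros((2 * n,) + grid)
    cohort.volumes[:, mask] = flat
    cohort.mask = mask
    return cohort, cube


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2 * (a & b).sum() / (a.sum() + b.sum())


@pytest.mark.parametrize("method", ["grf", "permutation"])
def test_planted_cluster_recovered(planted_cube_cohort, method):
    """Both corrections retain exactly the planted compact effect."""
    cohort, cube = planted_cube_cohort
    res = fit_voxelwise_glm(cohort)
    sel = cluster_correct(res, cohort.mask, method=method, n_perm=200, seed=4,
                          cohort=cohort)
    assert len(sel.clusters) >= 1
    assert _dice(sel.to_mask(), cube) >= 0.7


def test_stricter_voxel_threshold_never_grows_selection(planted_cube_cohort):
    cohort, _ = planted_cube_cohort
    res = fit_voxelwise_glm(cohort)
    loose = cluster_correct(res, cohort.mask, voxel_p=0.001)
    strict = cluster_correct(res, cohort.mask, voxel_p=0.0001)
    assert set(strict.indices).issubset(set(loose.indices))


def test_feature_matrix_extraction_identity(small_cohort):
    sel = select_high_variance_voxels(small_cohort, n_voxels=50)
    fm = extract_feature_matrix(small_cohort, sel, subjects="patient")
    assert fm.values.shape == (60, 50)
    assert np.all(np.diff(fm.voxel_indices) > 0)
    pat = small_cohort.indices("patient")
    flat = small_cohort.volumes[pat[3]].ravel()
    np.testing.assert_array_equal(fm.values[3], flat[fm.voxel_indices])


def test_empty_selection_refuses_feature_matrix(small_cohort):
    from subtyper.glm import SelectedVoxels

    empty = SelectedVoxels([], np.array([], dtype=int),
                           small_cohort.mask.shape, 0.001, 0.05, "grf")
    with pytest.raises(ValueError, match="no voxels"):
        extract_feature_matrix(small_cohort, empty)
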