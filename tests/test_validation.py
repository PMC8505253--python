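"""Effect sizes, factor-score tests with FDR, and score associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from subtyper import (
    SimConfig,
    bh_adjust,
    cohens_d,
    factor_tests,
    fit_voxelwise_glm,
    generate_cohort,
    score_association,
    subtype_contrast_maps,
)
from subtyper.validation import _nagelkerke

from conftest import brute_force_bh


class TestCohensD:
    def test_zero_for_identical_samples(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_two_sd_gap_equal_spread(self):
        # means 3 and 1, both sd 1, equal n -> d = 2
        assert cohens_d([2, 3, 4], [0, 1, 2]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        x, y = [2.0, 3.0, 4.5], [0.5, 1.0, 2.0]
        base = cohens_d(x, y)
        for c in (0.3, 7.0):
            scaled = cohens_d(np.multiply(x, c), np.multiply(y, c))
            assert scaled == pytest.approx(base)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestBH:
    def test_hand_step_up_fixture(self):
        rej, _ = bh_adjust([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert rej.tolist() == [True, True, True, False]

    def test_all_unit_p_no_rejection(self):
        rej, _ = bh_adjust([1.0] * 6, q=0.05)
        assert not rej.any()

    def test_single_test_reduces_to_raw_comparison(self):
        assert bh_adjust([0.04], q=0.05)[0].tolist() == [True]
        assert bh_adjust([0.06], q=0.05)[0].tolist() == [False]

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(1, 51))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            rej, p_adj = bh_adjust(p, q=0.05)
            assert rej.tolist() == brute_force_bh(p, 0.05).tolist()
            assert np.all(p_adj >= p - 1e-12)


class TestFactorTests:
    @staticmethod
    def _table(rng, n=40, shift=0.0):
        return pd.DataFrame({
            "grp": ["a"] * (n // 2) + ["b"] * (n // 2),
            "f1": np.concatenate([rng.standard_normal(n // 2) + shift,
                                  rng.standard_normal(n // 2)]),
            "f2": rng.standard_normal(n),
        })

    def test_strong_factor_detected_null_factor_not(self):
        tbl = self._table(np.random.default_rng(1), n=200, shift=1.5)
        out = factor_tests(tbl, "grp", ["f1", "f2"])
        assert bool(out.loc["f1", "significant"])
        assert out.loc["f1", "p_fdr"] >= out.loc["f1", "p_raw"]
        assert out.loc["f1", "cohens_d"] == pytest.approx(1.5, abs=0.5)
        assert out.loc["f1", "ci_low"] < out.loc["f1", "diff"] < out.loc["f1", "ci_high"]

    def test_untestable_factor_flagged_not_dropped(self):
        tbl = self._table(np.random.default_rng(2))
        tbl["f3"] = np.nan
        out = factor_tests(tbl, "grp", ["f1", "f2", "f3"])
        assert "f3" in out.index
        assert not bool(out.loc["f3", "testable"])

    def test_grouping_must_be_binary(self):
        tbl = self._table(np.random.default_rng(3))
        tbl.loc[0, "grp"] = "c"
        with pytest.raises(ValueError):
            factor_tests(tbl, "grp", ["f1"])


def _hand_logistic_fit(y, s):
    """Independent ML oracle: direct NLL minimization over (b0, b1)."""

    def nll(theta):
        eta = theta[0] + theta[1] * s
        return np.sum(np.log1p(np.exp(eta)) - y * eta)

    res = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    ll_full = -res.fun
    res0 = minimize(lambda t: nll([t[0], 0.0]), x0=[0.0], method="Nelder-Mead",
                    options={"xatol": 1e-12, "fatol": 1e-12})
    ll_null = -res0.fun
    return res.x[1], ll_null, ll_full


class TestScoreAssociation:
    def test_matches_independent_ml_oracle(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 10 + [0] * 10, dtype=float)
        s = np.concatenate([rng.standard_normal(10) + 1.0, rng.standard_normal(10)])
        assoc = score_association(y, pd.DataFrame({"s": s}), alpha=0.004)
        coef_hat, ll0, ll1 = _hand_logistic_fit(y, s)
        assert assoc.table.loc["s", "coef"] == pytest.approx(coef_hat, abs=1e-4)
        assert assoc.table.loc["s", "r2_nagelkerke"] == pytest.approx(
            _nagelkerke(ll0, ll1, len(y)), abs=1e-4
        )

    def test_null_score_explains_almost_nothing(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0.0, 1.0], 250)
        scores = pd.DataFrame({"s": rng.standard_normal(500)})
        assoc = score_association(y, scores)
        assert assoc.table.loc["s", "r2_nagelkerke"] < 0.02

    def test_separating_score_saturates_r2(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0.0, 1.0], 50)
        s = np.concatenate([rng.standard_normal(50), rng.standard_normal(50) + 4.0])
        assoc = score_association(y, pd.DataFrame({"s": s}))
        row = assoc.table.loc["s"]
        assert row["r2_nagelkerke"] >= 0.9
        assert np.isfinite(row["r2_nagelkerke"]) and row["r2_nagelkerke"] < 1.0

    def test_r2_invariant_to_affine_score_rescaling(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0.0, 1.0], 40)
        s = rng.standard_normal(80) + 0.8 * y
        r2a = score_association(y, pd.DataFrame({"s": s})).table["r2_nagelkerke"].iloc[0]
        r2b = score_association(
            y, pd.DataFrame({"s": 13.0 * s - 5.0})
        ).table["r2_nagelkerke"].iloc[0]
        assert r2a == pytest.approx(r2b, abs=1e-6)

    def test_best_fit_ranking_and_arm_size_guard(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0.0, 1.0], 30)
        scores = pd.DataFrame({
            "signal": rng.standard_normal(60) + 1.5 * y,
            "noise": rng.standard_normal(60),
        })
        assoc = score_association(y, scores)
        assert assoc.best_fit[0] == "signal"
        with pytest.raises(ValueError):
            score_association(np.array([0.0] * 50 + [1.0] * 5),
                              pd.DataFrame({"s": np.zeros(55)}))


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(n_patients=120, n_controls=100, grid_shape=(12, 12, 12),
                    effect_size=1.0, seed=19)
    cohort = generate_cohort(cfg)
    return cohort, cohort.truth.copy()


class TestContrastMaps:
    def test_signs_match_planted_pattern(self, planted):
        from subtyper.simulate import default_regions

        cohort, labels = planted
        contrasts = subtype_contrast_maps(cohort, labels)
        frontal, posterior = default_regions(cohort.mask)
        mask_flat = np.flatnonzero(cohort.mask.ravel())
        f_cols = np.searchsorted(mask_flat, frontal)
        p_cols = np.searchsorted(mask_flat, posterior)
        c0 = next(c for c in contrasts if c.subtype == 0)
        # subtype 0 planted as frontal +, posterior -
        assert (c0.t[f_cols] > 0).mean() >= 0.95
        assert (c0.t[p_cols] < 0).mean() >= 0.95
        # d and t share sign wherever t is non-negligible
        strong = np.abs(c0.t) > 1
        assert np.all(np.sign(c0.d[strong]) == np.sign(c0.t[strong]))

    def test_voxelwise_t_equals_subset_glm(self, planted):
        cohort, labels = planted
        contrasts = subtype_contrast_maps(cohort, labels)
        c0 = next(c for c in contrasts if c.subtype == 0)
        sid = cohort.phenotypes["subject_id"]
        members = labels.index[labels == 0]
        subset = np.concatenate([
            np.flatnonzero(sid.isin(members).to_numpy()),
            cohort.indices("control"),
        ])
        direct = fit_voxelwise_glm(cohort, subset=subset)
        np.testing.assert_allclose(c0.t, direct.t, atol=1e-10)

    def test_tiny_subtype_refused(self, planted):
        cohort, labels = planted
        bad = labels.copy()
        bad.iloc[:] = 0
        bad.iloc[:2] = 1  # subtype with 2 members
        with pytest.raises(ValueError, match="refused"):
            subtype_contrast_maps(cohort, bad)
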