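"""Unit and property tests for the two-part model fitting and LRT."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sda.core import (
    DegenerateFeatureError,
    DesignMatrix,
    FeatureVector,
    NonIdentifiableError,
    classify_feature,
    fit_feature,
    fit_joint,
    fit_nonzero_part,
    fit_zero_part,
    gaussian_kernel,
    lrt_test,
    select_bandwidth,
    smoothed_loglik_nonzero,
)
from sda.core import test_feature as run_feature_test

from conftest import grid_search_beta, null_two_group_feature, two_group_design


# ---------------------------------------------------------------------------
# kernel and bandwidth


@pytest.mark.parametrize("u, expected", [(0.0, 0.3989423), (1.0, 0.2419707)])
def test_gaussian_kernel_values(u, expected):
    assert gaussian_kernel(u) == pytest.approx(expected, abs=1e-7)


@given(st.floats(-10, 10))
def test_gaussian_kernel_symmetric(u):
    assert gaussian_kernel(u) == pytest.approx(gaussian_kernel(-u), rel=1e-12)


def test_gaussian_kernel_integrates_to_one():
    grid = np.linspace(-10, 10, 20001)
    assert np.trapezoid(gaussian_kernel(grid), grid) == pytest.approx(1.0, abs=1e-8)


def test_bandwidth_rule():
    # sd = 1, N = 32: 32^(1/5) = 2 so h = 1.144 / 2
    vals = np.array([4.0, 5.0, 6.0])
    sd = np.std(vals, ddof=1)
    assert select_bandwidth(vals / sd, 32) == pytest.approx(0.572)
    # h scales linearly in sigma-hat
    assert select_bandwidth(2 * vals / sd, 32) == pytest.approx(1.144)


def test_bandwidth_degenerate_inputs():
    with pytest.raises(DegenerateFeatureError):
        select_bandwidth(np.array([3.0, 3.0, 3.0]), 10)
    with pytest.raises(DegenerateFeatureError):
        select_bandwidth(np.array([3.0]), 10)


# ---------------------------------------------------------------------------
# zero part


def test_zero_part_saturated_two_group():
    # zero fractions 2/4 at x=0 and 1/5 at x=1: saturated logistic has
    # closed-form group log-odds
    delta = np.array([1, 1, 0, 0, 1, 0, 0, 0, 0], float)
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1], float)[:, None]
    fit = fit_zero_part(delta, x)
    assert not fit.separated
    assert fit.gamma0 == pytest.approx(0.0, abs=1e-8)
    assert fit.gamma[0] == pytest.approx(np.log(0.2 / 0.8), abs=1e-7)


def test_zero_part_intercept_only():
    delta = np.array([1, 0, 0, 0] * 3, float)
    fit = fit_zero_part(delta, np.empty((12, 0)))
    assert fit.gamma0 == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
    expected_ll = 3 * np.log(0.25) + 9 * np.log(0.75)
    assert fit.loglik == pytest.approx(expected_ll, abs=1e-10)


def test_zero_part_quasi_separation_flagged():
    # group x=1 is all non-zero: the group-effect MLE diverges
    delta = np.array([1, 1, 0, 0, 0, 0, 0, 0], float)
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)[:, None]
    fit = fit_zero_part(delta, x)
    assert fit.separated
    assert np.isfinite(fit.loglik)


def test_zero_part_constant_delta_raises():
    with pytest.raises(DegenerateFeatureError):
        fit_zero_part(np.zeros(6), np.arange(6.0)[:, None])


def test_zero_part_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    x = rng.normal(size=(80, 2))
    eta = 0.3 - 0.8 * x[:, 0] + 0.5 * x[:, 1]
    delta = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_zero_part(delta, x)
    ref = sm.Logit(delta, sm.add_constant(x)).fit(disp=0)
    assert not fit.separated
    np.testing.assert_allclose(np.r_[fit.gamma0, fit.gamma], ref.params, atol=1e-6)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)


# ---------------------------------------------------------------------------
# smoothed non-zero likelihood


def test_smoothed_loglik_single_point():
    ll = smoothed_loglik_nonzero(np.zeros(1), np.array([3.0]), np.array([[1.0]]), 1.0)
    assert ll == pytest.approx(np.log(gaussian_kernel(0.0)), abs=1e-7)


def test_smoothed_loglik_two_equal_residuals():
    ll = smoothed_loglik_nonzero(np.zeros(1), np.array([2.0, 2.0]),
                                 np.array([[1.0], [1.0]]), 1.0)
    assert ll == pytest.approx(2 * np.log(gaussian_kernel(0.0)), abs=1e-7)


@given(st.floats(-5, 5))
def test_smoothed_loglik_location_invariant(shift):
    # adding a constant to every log value leaves residual differences
    # unchanged: the model has no intercept and the location sits in f
    rng = np.random.default_rng(7)
    logy = rng.normal(5, 1, 15)
    x = rng.normal(size=(15, 1))
    beta = np.array([0.4])
    a = smoothed_loglik_nonzero(beta, logy, x, 0.5)
    b = smoothed_loglik_nonzero(beta, logy + shift, x, 0.5)
    assert a == pytest.approx(b, abs=1e-9)


def test_smoothed_loglik_gradient_matches_finite_differences(rng):
    from sda.core import _smoothed_nonzero_objective

    logy = rng.normal(5, 1, 20)
    x = rng.normal(size=(20, 2))
    beta = np.array([0.3, -0.5])
    _, grad = _smoothed_nonzero_objective(beta, logy, x, 0.4)
    eps = 1e-6
    for k in range(2):
        bp, bm = beta.copy(), beta.copy()
        bp[k] += eps
        bm[k] -= eps
        fd = (smoothed_loglik_nonzero(bp, logy, x, 0.4)
              - smoothed_loglik_nonzero(bm, logy, x, 0.4)) / (2 * eps)
        assert grad[k] == pytest.approx(fd, abs=1e-5)


# ---------------------------------------------------------------------------
# non-zero fit


def test_nonzero_fit_exact_twofold_shift(rng):
    # group 1 is exactly 2x group 0 on the raw scale: the smoothed
    # likelihood peaks at beta = log 2 (grid-search oracle agrees)
    base = rng.normal(5, 1, 10)
    logy = np.concatenate([base, base + np.log(2)])
    x = np.array([0.0] * 10 + [1.0] * 10)[:, None]
    h = select_bandwidth(logy, 20)
    fit = fit_nonzero_part(logy, x, h)
    assert fit.converged
    assert fit.beta[0] == pytest.approx(np.log(2), abs=1e-6)
    assert grid_search_beta(logy, x, h) == pytest.approx(np.log(2), abs=2e-4)


def test_nonzero_fit_matchesgrid_search_beta(rng):
    for _ in range(5):
        n = int(rng.integers(8, 30))
        x = np.array([0.0] * (n // 2) + [1.0] * (n - n // 2))[:, None]
        logy = rng.normal(5, 1, n) + 0.5 * x[:, 0]
        h = select_bandwidth(logy, n)
        fit = fit_nonzero_part(logy, x, h)
        oracle = grid_search_beta(logy, x, h)
        assert abs(oracle) < 1.95  # interior to the grid
        assert fit.beta[0] == pytest.approx(oracle, abs=2e-4)


def test_nonzero_fit_normal_limit_near_ols(rng):
    # with normal errors and no zeros the estimator agrees with least
    # squares up to Monte-Carlo error (mean difference over replicates ~ 0)
    n = 200
    diffs = []
    for _ in range(10):
        x = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])[:, None]
        logy = 5 + 0.7 * x[:, 0] + rng.normal(0, 1, n)
        h = select_bandwidth(logy, n)
        fit = fit_nonzero_part(logy, x, h)
        ols = np.linalg.lstsq(np.column_stack([np.ones(n), x]), logy, rcond=None)[0][1]
        diffs.append(fit.beta[0] - ols)
    assert abs(np.mean(diffs)) < 0.05


def test_nonzero_fit_constant_covariate_raises(rng):
    logy = rng.normal(size=8)
    with pytest.raises(NonIdentifiableError):
        fit_nonzero_part(logy, np.ones((8, 1)), 0.5)


# ---------------------------------------------------------------------------
# feature orchestration, modes and LRT


def test_feature_mode_classification():
    both = FeatureVector("a", [0, 1.5, 2.0, 0, 3.0, 4.0])
    no_zeros = FeatureVector("b", [1.0, 2.0, 3.0, 4.0, 1.5, 2.5])
    all_zeros = FeatureVector("c", [0.0] * 6)
    one_nonzero = FeatureVector("d", [0, 0, 0, 0, 0, 2.0])
    assert classify_feature(both) == "both_parts"
    assert classify_feature(no_zeros) == "nonzero_only"
    assert classify_feature(all_zeros) == "skipped"
    assert classify_feature(one_nonzero) == "zero_only"


def test_lrt_chi2_reference():
    from sda.core import FeatureFit, ZeroPartFit, NonzeroPartFit

    zero_null = ZeroPartFit(0.0, np.zeros(1), -10.0)
    zero_full = ZeroPartFit(0.0, np.zeros(1), -9.0)
    nz_null = NonzeroPartFit(np.zeros(1), 0.5, -21.0, 10)
    nz_full = NonzeroPartFit(np.zeros(1), 0.5, -19.0045, 10)
    fit = FeatureFit("f", "both_parts", 0.5, zero_full, nz_full, zero_null, nz_null)
    res = lrt_test(fit)
    assert res.lrt == pytest.approx(5.991, abs=1e-3)
    assert res.df == 2
    assert res.pvalue == pytest.approx(0.05, abs=1e-4)


def test_lrt_identical_fits_gives_p_one(rng, design_50_50):
    y = null_two_group_feature(rng)
    fit = fit_feature(FeatureVector("f", y), design_50_50)
    fit.null_zero, fit.null_nonzero = fit.full_zero, fit.full_nonzero
    res = lrt_test(fit, design_50_50)
    assert res.lrt == 0.0
    assert res.pvalue == 1.0


def test_lrt_bandwidth_mismatch_rejected(rng, design_50_50):
    y = null_two_group_feature(rng)
    fit = fit_feature(FeatureVector("f", y), design_50_50)
    fit.null_nonzero.h *= 2
    with pytest.raises(ValueError, match="bandwidth"):
        lrt_test(fit, design_50_50)


def test_full_model_never_below_null(rng, design_50_50):
    # nested-model monotonicity over random semicontinuous features
    for i in range(25):
        y = null_two_group_feature(rng, p_zero=float(rng.uniform(0.05, 0.7)))
        fit = fit_feature(FeatureVector(f"f{i}", y), design_50_50)
        assert fit.loglik("full") >= fit.loglik("null") - 1e-6


def test_joint_and_partwise_fits_agree(rng, design_50_50):
    # the joint likelihood factorizes into the logistic and smoothed parts
    for i in range(10):
        y = null_two_group_feature(rng, p_zero=0.3)
        fv = FeatureVector(f"f{i}", y)
        fit = fit_feature(fv, design_50_50)
        g0, g, b, ll = fit_joint(fv, design_50_50)
        assert g0 == pytest.approx(fit.full_zero.gamma0, abs=1e-6)
        np.testing.assert_allclose(g, fit.full_zero.gamma, atol=1e-6)
        beta = fit.full_nonzero.beta
        np.testing.assert_allclose(b, beta[np.isfinite(beta)], atol=1e-6)
        assert ll == pytest.approx(fit.loglik("full"), abs=1e-6)


@pytest.mark.parametrize("scale", [1e-3, 0.5, 7.0, 1e3])
def test_rescaling_abundance_preserves_test(rng, design_50_50, scale):
    # positive rescaling shifts all log values equally; beta, the LRT and
    # the p-value are unchanged
    y = null_two_group_feature(rng, p_zero=0.3)
    r1 = run_feature_test(FeatureVector("f", y), design_50_50)
    r2 = run_feature_test(FeatureVector("f", y * scale), design_50_50)
    assert r2.beta_hat_q == pytest.approx(r1.beta_hat_q, abs=1e-6)
    assert r2.lrt == pytest.approx(r1.lrt, abs=1e-6)
    assert r2.pvalue == pytest.approx(r1.pvalue, abs=1e-6)


def test_no_zero_feature_uses_single_df(design_50_50, rng):
    y = np.exp(rng.normal(5, 1, 100))
    res = run_feature_test(FeatureVector("f", y), design_50_50)
    assert res.mode == "nonzero_only"
    assert res.df == 1
    assert np.isnan(res.gamma_hat_q)
    assert np.isfinite(res.pvalue)


def test_all_zero_feature_skipped(design_50_50):
    res = run_feature_test(FeatureVector("f", np.zeros(100)), design_50_50)
    assert res.mode == "skipped"
    assert np.isnan(res.pvalue)


def test_null_pvalues_uniform_small_scale(rng, design_50_50):
    # quick calibration check; the full-scale version lives in the
    # acceptance suite
    ps = []
    for i in range(200):
        y = null_two_group_feature(rng, p_zero=0.3, censor=False)
        ps.append(run_feature_test(FeatureVector(f"f{i}", y), design_50_50).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 1e-3
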