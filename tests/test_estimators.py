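"""Estimators: Wald ratio, IVW, weighted median, MR-Egger, inference helpers."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_h, make_harmonized
from tsmr import (
    bonferroni_threshold,
    ivw,
    mr_egger,
    wald_inference,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from tsmr.mr_estimators import (
    Z975,
    DegenerateInstrumentError,
    SingularDesignError,
)
from tsmr.sumstats_io import EmptyInputError, format_sig


# ---------------------------------------------------------------------------
# Wald ratio


def test_wald_ratio_direct_arithmetic():
    est = wald_ratio(make_h(bx=0.1, by=0.02, sy=0.005))
    assert math.isclose(est.theta, 0.2)
    assert math.isclose(est.se_theta, 0.05)
    assert math.isclose(est.weight, 400.0)


def test_wald_ratio_null_outcome_effect():
    est = wald_ratio(make_h(bx=0.1, by=0.0, sy=0.005))
    assert est.theta == 0.0 and math.isclose(est.se_theta, 0.05)


def test_wald_ratio_allele_recoding_invariance():
    a = wald_ratio(make_h(bx=0.1, by=0.02, sy=0.005))
    b = wald_ratio(make_h(bx=-0.1, by=-0.02, sy=0.005))
    assert math.isclose(a.theta, b.theta) and math.isclose(a.weight, b.weight)


def test_wald_ratio_zero_exposure_effect_is_degenerate():
    with pytest.raises(DegenerateInstrumentError):
        wald_ratio(make_h(bx=0.0))


# ---------------------------------------------------------------------------
# IVW


def test_ivw_single_instrument_reduces_to_wald_ratio():
    h = make_h(bx=0.1, by=0.02, sy=0.005)
    res, ratio = ivw([h]), wald_ratio(h)
    assert math.isclose(res.beta, ratio.theta)
    assert math.isclose(res.se, ratio.se_theta)


def test_ivw_equal_weights_hand_summed():
    # three instruments, each with weight 1/0.1^2 = 100
    hs = make_harmonized(bx=[1, 1, 1], by=[0.2, 0.3, 0.1], sy=0.1)
    res = ivw(hs)
    assert math.isclose(res.beta, 0.2)
    assert math.isclose(res.se, math.sqrt(1 / 300))
    assert res.n_snps == 3


def test_ivw_matches_wls_through_origin_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    bx = rng.uniform(0.03, 0.3, 25) * rng.choice([-1, 1], 25)
    sy = rng.uniform(0.01, 0.05, 25)
    by = 0.25 * bx + rng.normal(0, sy)
    hs = make_harmonized(bx, by, sy)
    fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
    assert math.isclose(ivw(hs).beta, float(fit.params[0]), rel_tol=1e-10)


def test_ivw_empty_and_degenerate_inputs():
    with pytest.raises(EmptyInputError):
        ivw([])
    with pytest.raises(DegenerateInstrumentError):
        ivw([make_h(bx=0.0), make_h(vid="v2")])


# ---------------------------------------------------------------------------
# weighted median


def test_weighted_median_degenerate_distribution():
    hs = make_harmonized(bx=[0.1, 0.2, 0.4], by=[0.02, 0.04, 0.08], sy=[0.01, 0.03, 0.02])
    res = weighted_median(hs, seed=1)
    assert math.isclose(res.beta, 0.2)  # all ratios equal 0.2, any weights


def test_weighted_median_equal_weights_takes_middle_theta():
    # s_2 = 0.5 exactly, so the interpolation returns the middle ratio
    hs = make_harmonized(bx=[1, 1, 1], by=[0.1, 0.2, 0.3], sy=0.1)
    assert math.isclose(weighted_median_point(hs), 0.2)


def test_weighted_median_interpolation_formula_by_hand():
    # weights 1:3 after normalization, so s = (0.125, 0.625); at s = 0.5:
    # beta = 0.1 + (0.3 - 0.1) * (0.5 - 0.125) / (0.625 - 0.125) = 0.25
    hs = make_harmonized(bx=[1, 1], by=[0.1, 0.3], sy=[0.2, 0.2 / math.sqrt(3)])
    assert math.isclose(weighted_median_point(hs), 0.25)


def test_weighted_median_requires_three_instruments_and_warns_on_small_bootstrap():
    hs = make_harmonized(bx=[0.1, 0.2], by=[0.02, 0.04], sy=0.01)
    with pytest.raises(ValueError, match="3 instruments"):
        weighted_median(hs, seed=1)
    hs3 = make_harmonized(bx=[0.1, 0.2, 0.3], by=[0.02, 0.04, 0.06], sy=0.01)
    with pytest.warns(UserWarning, match="bootstrap"):
        weighted_median(hs3, n_boot=50, seed=1)


def test_weighted_median_reproducible_given_seed():
    hs = make_harmonized(bx=[0.1, 0.2, 0.3], by=[0.01, 0.05, 0.07], sy=[0.01, 0.02, 0.03])
    a = weighted_median(hs, seed=7)
    b = weighted_median(hs, seed=7)
    assert a == b


@given(st.lists(
    st.tuples(
        st.floats(0.02, 0.5), st.booleans(),
        st.floats(-0.5, 0.5), st.floats(0.005, 0.1),
    ),
    min_size=3, max_size=20,
))
def test_weighted_median_lies_within_ratio_range(rows):
    bx = np.array([r[0] * (-1 if r[1] else 1) for r in rows])
    by = np.array([r[2] for r in rows])
    sy = np.array([r[3] for r in rows])
    hs = make_harmonized(bx, by, sy)
    thetas = by / bx
    beta = weighted_median_point(hs)
    assert thetas.min() - 1e-12 <= beta <= thetas.max() + 1e-12


# ---------------------------------------------------------------------------
# MR-Egger


def test_mr_egger_recovers_exact_linear_relation():
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    by = 0.01 + 0.3 * bx
    res = mr_egger(make_harmonized(bx, by, sy=[0.01, 0.02, 0.03, 0.01]))
    assert math.isclose(res.intercept, 0.01, abs_tol=1e-12)
    assert math.isclose(res.beta, 0.3, abs_tol=1e-12)


def test_mr_egger_through_origin_gives_zero_intercept():
    bx = np.array([0.05, 0.1, 0.2, 0.3])
    res = mr_egger(make_harmonized(bx, 0.4 * bx, sy=0.02))
    assert math.isclose(res.intercept, 0.0, abs_tol=1e-12)
    assert math.isclose(res.beta, 0.4, abs_tol=1e-12)


def test_mr_egger_matches_general_wls_oracle_including_inference():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    bx = rng.uniform(0.03, 0.3, 30)
    sy = rng.uniform(0.01, 0.04, 30)
    by = 0.015 + 0.3 * bx + rng.normal(0, 5 * sy)  # overdispersed: scale > 1
    hs = make_harmonized(bx, by, sy)
    res = mr_egger(hs)
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    assert fit.scale > 1  # the dispersion floor is inactive here
    assert math.isclose(res.intercept, float(fit.params[0]), rel_tol=1e-10)
    assert math.isclose(res.beta, float(fit.params[1]), rel_tol=1e-10)
    assert math.isclose(res.intercept_se, float(fit.bse[0]), rel_tol=1e-10)
    assert math.isclose(res.se, float(fit.bse[1]), rel_tol=1e-10)
    assert math.isclose(res.pval, float(fit.pvalues[1]), rel_tol=1e-9)


def test_mr_egger_orients_exposure_effects_positive():
    bx = np.array([0.05, -0.1, 0.2, -0.3])
    by = 0.01 + 0.3 * bx
    flipped = mr_egger(make_harmonized(bx, by, sy=0.02))
    oriented = mr_egger(make_harmonized(np.abs(bx), np.where(bx < 0, -by, by), sy=0.02))
    assert math.isclose(flipped.beta, oriented.beta)
    assert math.isclose(flipped.intercept, oriented.intercept)


def test_mr_egger_degenerate_design_and_minimum_instruments():
    with pytest.raises(SingularDesignError):
        mr_egger(make_harmonized([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], sy=0.01))
    with pytest.raises(ValueError, match="3 instruments"):
        mr_egger(make_harmonized([0.1, 0.2], [0.01, 0.02], sy=0.01))


# ---------------------------------------------------------------------------
# shared invariances


def _random_hs(seed, m=15):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.03, 0.3, m) * rng.choice([-1, 1], m)
    sy = rng.uniform(0.01, 0.05, m)
    by = 0.2 * bx + rng.normal(0, sy)
    sx = rng.uniform(0.002, 0.008, m)
    return bx, by, sy, sx


def test_all_estimators_invariant_under_allele_recoding():
    bx, by, sy, sx = _random_hs(8)
    hs = make_harmonized(bx, by, sy, sx)
    flip = np.where(np.arange(len(bx)) % 2 == 0, -1, 1)
    hs_flipped = make_harmonized(bx * flip, by * flip, sy, sx)
    assert math.isclose(ivw(hs).beta, ivw(hs_flipped).beta, rel_tol=1e-12)
    assert math.isclose(ivw(hs).se, ivw(hs_flipped).se, rel_tol=1e-12)
    assert math.isclose(
        weighted_median_point(hs), weighted_median_point(hs_flipped), rel_tol=1e-12
    )
    a, b = mr_egger(hs), mr_egger(hs_flipped)
    assert math.isclose(a.beta, b.beta, rel_tol=1e-12)
    assert math.isclose(a.intercept, b.intercept, rel_tol=1e-12)
    assert math.isclose(a.se, b.se, rel_tol=1e-12)


def test_estimators_invariant_to_instrument_ordering():
    bx, by, sy, sx = _random_hs(9)
    hs = make_harmonized(bx, by, sy, sx)
    perm = np.random.default_rng(1).permutation(len(hs))
    hs_perm = [hs[i] for i in perm]
    assert math.isclose(ivw(hs).beta, ivw(hs_perm).beta, rel_tol=1e-12)
    assert math.isclose(weighted_median_point(hs), weighted_median_point(hs_perm), rel_tol=1e-12)
    assert math.isclose(mr_egger(hs).beta, mr_egger(hs_perm).beta, rel_tol=1e-12)


# ---------------------------------------------------------------------------
# inference helpers


def test_bonferroni_thresholds():
    assert bonferroni_threshold(25) == 0.002
    assert format_sig(bonferroni_threshold(41)) == "0.00122"
    assert bonferroni_threshold(1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


def test_wald_inference_null_estimate():
    lo, hi, p = wald_inference(0.0, 0.3)
    assert p == 1.0
    assert math.isclose(lo, -hi)


def test_wald_inference_normal_quantile_identity():
    lo, hi, p = wald_inference(Z975, 1.0)
    assert math.isclose(p, 0.05, rel_tol=1e-9)
    assert math.isclose(lo, 0.0, abs_tol=1e-12)


def test_wald_inference_reproduces_published_style_interval():
    """beta 0.168 with SE 0.0380 gives the 95% CI (0.093, 0.242) to the
    precision at which such tables print it."""
    lo, hi, _ = wald_inference(0.168, 0.0380)
    assert abs(lo - 0.093) < 1e-3
    assert abs(hi - 0.242) < 1e-3


def test_wald_inference_rejects_nonpositive_se():
    with pytest.raises(ValueError):
        wald_inference(0.1, 0.0)


def test_wald_inference_t_reference_is_wider_than_normal():
    lo_n, hi_n, p_n = wald_inference(0.2, 0.1)
    lo_t, hi_t, p_t = wald_inference(0.2, 0.1, df=5)
    assert lo_t < lo_n and hi_t > hi_n and p_t > p_n
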