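"""Causal estimators for summary-data Mendelian randomization.

Given m harmonized instruments with exposure effects beta_x (SE se_x) and
outcome effects beta_y (SE se_y), the per-variant Wald ratio is

    theta_j = beta_yj / beta_xj,   se(theta_j) = se_yj / |beta_xj|   (first order),

with inverse-variance weight w_j = 1 / se(theta_j)^2 = beta_xj^2 / se_yj^2.

* IVW: beta = sum(w_j theta_j) / sum(w_j), fixed-effect SE = sqrt(1/sum w_j);
  equivalent to weighted least squares of beta_y on beta_x through the
  origin with weights 1/se_y^2 (and to two-stage least squares on
  individual-level data when instruments are uncorrelated).
* Weighted median: the 50% point of the inverse-variance-weighted empirical
  distribution of the theta_j, consistent when instruments carrying more
  than half of the weight are valid; SE by parametric bootstrap.
* MR-Egger: weighted regression of beta_y on beta_x *with* an intercept;
  the slope is a pleiotropy-corrected causal estimate and the intercept the
  average directional pleiotropy (interpretable under InSIDE).  Inference
  uses t(m - 2) with the residual dispersion floored at 1.

IVW and weighted-median inference uses normal quantiles.  The 95% multiplier
is the exact 0.975 quantile, not 1.96.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument
from .sumstats_io import EmptyInputError, MRResult

logger = logging.getLogger(__name__)

Z975 = float(stats.norm.ppf(0.975))
_TINY_P = float(np.finfo(float).tiny)

DEFAULT_N_BOOT = 1000
MIN_N_BOOT = 100


class DegenerateInstrumentError(ValueError):
    """An instrument has a zero exposure effect; its ratio is undefined."""


class SingularDesignError(ValueError):
    """All exposure effects are equal; the Egger regression is not identified."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with its first-order SE and IVW weight."""

    variant_id: str
    theta: float
    se_theta: float
    weight: float


def wald_inference(
    beta: float, se: float, df: int | None = None
) -> tuple[float, float, float]:
    """95% CI and two-sided p for beta/se, under normal or t(df) reference."""
    if se <= 0:
        raise ValueError("se must be positive")
    if df is None:
        q = Z975
        pval = 2.0 * stats.norm.sf(abs(beta / se))
    else:
        q = float(stats.t.ppf(0.975, df))
        pval = 2.0 * stats.t.sf(abs(beta / se), df)
    pval = float(min(1.0, max(pval, _TINY_P)))
    return beta - q * se, beta + q * se, pval


def wald_ratio(h: HarmonizedInstrument) -> RatioEstimate:
    """Single-instrument causal estimate beta_y / beta_x."""
    if h.beta_x == 0:
        raise DegenerateInstrumentError(f"{h.variant_id}: beta_x = 0")
    theta = h.beta_y / h.beta_x
    se_theta = h.se_y / abs(h.beta_x)
    return RatioEstimate(h.variant_id, theta, se_theta, 1.0 / se_theta**2)


def _arrays(hs: Sequence[HarmonizedInstrument]):
    if len(hs) == 0:
        raise EmptyInputError("no instruments supplied")
    bx = np.array([h.beta_x for h in hs], dtype=float)
    sx = np.array([h.se_x for h in hs], dtype=float)
    by = np.array([h.beta_y for h in hs], dtype=float)
    sy = np.array([h.se_y for h in hs], dtype=float)
    if np.any(bx == 0):
        raise DegenerateInstrumentError("an instrument has beta_x = 0")
    return bx, sx, by, sy


def ivw(hs: Sequence[HarmonizedInstrument]) -> MRResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios."""
    bx, _, by, sy = _arrays(hs)
    theta = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    lo, hi, pval = wald_inference(beta, se)
    return MRResult("IVW", beta, se, lo, hi, pval, n_snps=len(hs))


def _wm_point(theta: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized cumulative
    weights s_j = cum(w'_j) - w'_j / 2 at s = 0.5 (boundary theta outside)."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = weight[order] / weight.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, th))


def weighted_median_point(hs: Sequence[HarmonizedInstrument]) -> float:
    """Weighted-median causal estimate without bootstrap inference."""
    bx, _, by, sy = _arrays(hs)
    return _wm_point(by / bx, bx**2 / sy**2)


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Each bootstrap replicate redraws beta_x and beta_y from normal(beta, se)
    and recomputes the weighted median; the SE is the standard deviation of
    the replicates.  CI and p-value use normal quantiles.
    """
    if len(hs) < 3:
        raise ValueError("weighted_median requires at least 3 instruments")
    if n_boot < MIN_N_BOOT:
        warnings.warn(
            f"n_boot = {n_boot} < {MIN_N_BOOT}: bootstrap SE will be unreliable",
            UserWarning,
            stacklevel=2,
        )
    bx, sx, by, sy = _arrays(hs)
    beta = _wm_point(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, len(hs)))
    bys = rng.normal(by, sy, size=(n_boot, len(hs)))
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = bys / bxs
        weights = bxs**2 / sy**2
    est = np.empty(n_boot)
    for i in range(n_boot):
        est[i] = _wm_point(thetas[i], weights[i])
    se = float(np.std(est, ddof=1))
    lo, hi, pval = wald_inference(beta, se)
    return MRResult("weighted_median", beta, se, lo, hi, pval, n_snps=len(hs))


def mr_egger(hs: Sequence[HarmonizedInstrument]) -> MRResult:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Instruments are first oriented so beta_x >= 0 (both betas negated where
    beta_x < 0), which the intercept's interpretation requires.  Weights are
    1/se_y^2; coefficient covariance is scaled by the residual dispersion
    floored at 1; p-values and CIs use t(m - 2).
    """
    if len(hs) < 3:
        raise ValueError("mr_egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(hs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise SingularDesignError("all exposure effects equal after orientation")

    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    df = len(hs) - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2) / df))
    cov = sigma2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_intercept, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    lo, hi, pval = wald_inference(slope, se_slope, df=df)
    ilo, ihi, ipval = wald_inference(intercept, se_intercept, df=df)
    return MRResult(
        "mr_egger",
        slope,
        se_slope,
        lo,
        hi,
        pval,
        n_snps=len(hs),
        intercept=intercept,
        intercept_se=se_intercept,
        intercept_ci_low=ilo,
        intercept_ci_high=ihi,
        intercept_pval=ipval,
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Exact alpha / n_tests (the reporting layer rounds to 3 s.f.)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
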