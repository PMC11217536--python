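"""Causal-effect estimators for two-sample MR on summary statistics.

Let β_Xj ± se_Xj and β_Yj ± se_Yj be the harmonized per-SNP effects of
variant j on exposure and outcome.  The per-SNP Wald ratio is
θ̂_j = β_Yj / β_Xj with first-order (delta-method) standard error
se_Yj / |β_Xj|.  The inverse-variance-weighted (IVW) estimate pools the
ratios with weights w_j = β_Xj² / se_Yj² — algebraically, weighted least
squares of β_Y on β_X through the origin.  MR-Egger adds an unconstrained
intercept (directional-pleiotropy term); the weighted median interpolates
the ratio at cumulative weight 1/2; maximum likelihood fits the joint
measurement-error model β_Xj ~ N(ξ_j, se_Xj²), β_Yj ~ N(θ·ξ_j, se_Yj²).

All estimates are reported on the log-odds scale with OR = exp(β) and
normal-theory confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (ConvergenceError, DegenerateInstrumentError,
                     InsufficientInstrumentsError)
from .harmonize import HarmonizedSet

METHODS = ("wald", "ivw_fixed", "ivw_random", "egger_slope", "egger_intercept",
           "weighted_median", "max_likelihood")


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    pvalue: float
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    exposure: str = ""
    outcome: str = ""
    model_selected: str | None = None  # fixed/random branch taken under "auto"
    note: str = ""


def to_odds_ratio(beta: float, se: float, level: float = 0.95):
    """OR = exp(beta) with level-% CI exp(beta ∓ z·se)."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def _two_sided_p(beta: float, se: float) -> float:
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return max(min(p, 1.0), np.nextafter(0.0, 1.0))


def _estimate(method: str, n_snp: int, beta: float, se: float,
              weights=None, level: float = 0.95, **extra) -> MREstimate:
    or_value, ci_low, ci_high = to_odds_ratio(beta, se, level)
    return MREstimate(
        method=method, n_snp=n_snp, beta=float(beta), se=float(se),
        or_value=or_value, ci_low=ci_low, ci_high=ci_high,
        pvalue=_two_sided_p(beta, se),
        weights=np.asarray(weights if weights is not None else [], dtype=float),
        **extra)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with delta-method SE |se_Y/β_X|.

    The first-order SE ignores the exposure-side uncertainty — the same
    convention that underlies the IVW weights.
    """
    if bx == 0:
        raise DegenerateInstrumentError("exposure effect is 0; Wald ratio undefined")
    if sx <= 0 or sy <= 0:
        raise ValueError("standard errors must be > 0")
    return _estimate("wald", 1, by / bx, abs(sy / bx))


def _ratio_weights(hset: HarmonizedSet):
    """Per-SNP Wald ratios θ̂_j and IVW weights w_j = β_Xj²/se_Yj²."""
    bx = hset.beta_exposure
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    ratios = hset.beta_outcome / bx
    weights = bx ** 2 / hset.se_outcome ** 2
    return ratios, weights


def _q_statistic(ratios: np.ndarray, weights: np.ndarray, pooled: float) -> float:
    return float(np.sum(weights * (ratios - pooled) ** 2))


def ivw(hset: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate (the primary MR analysis).

    ``model``: "fixed" uses se = (Σw)^(-1/2); "random" multiplies it by
    max(1, sqrt(Q/(J−1))) (multiplicative overdispersion); "auto" picks
    random when Cochran's Q has p < 0.05 and fixed otherwise, recording the
    branch in ``model_selected``.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"model must be fixed/random/auto, got {model!r}")
    J = hset.n_snp
    if J == 0:
        raise InsufficientInstrumentsError("IVW needs at least 1 instrument")
    ratios, weights = _ratio_weights(hset)
    sw = float(weights.sum())
    beta = float(np.sum(weights * ratios) / sw)
    se_fixed = sw ** -0.5
    if J == 1:
        warnings.warn("IVW on a single instrument reduces to the Wald ratio",
                      stacklevel=2)
        return _estimate("ivw_fixed", 1, float(ratios[0]),
                         float(hset.se_outcome[0] / abs(hset.beta_exposure[0])),
                         weights, model_selected="fixed",
                         note="single-instrument Wald ratio")
    q = _q_statistic(ratios, weights, beta)
    scale = max(1.0, math.sqrt(q / (J - 1)))
    if model == "auto":
        q_pvalue = stats.chi2.sf(q, J - 1)
        model = "random" if q_pvalue < 0.05 else "fixed"
    if model == "random":
        return _estimate("ivw_random", J, beta, se_fixed * scale, weights,
                         model_selected="random")
    return _estimate("ivw_fixed", J, beta, se_fixed, weights, model_selected="fixed")


def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Each SNP is first oriented so β_Xj ≥ 0 (both signs flipped together,
    which leaves the Wald ratio unchanged); then β_Y is regressed on β_X
    with an unconstrained intercept, weights 1/se_Y².  SEs use multiplicative
    overdispersion floored at 1 with J−2 degrees of freedom.  An intercept
    p < 0.05 flags directional horizontal pleiotropy.
    """
    J = hset.n_snp
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {J}")
    sign = np.where(hset.beta_exposure < 0, -1.0, 1.0)
    bx = sign * hset.beta_exposure
    by = sign * hset.beta_outcome
    w = 1.0 / hset.se_outcome ** 2

    # closed-form 2-parameter WLS: solve (X' W X) c = X' W y for [intercept, slope]
    sw = w.sum()
    swx = (w * bx).sum()
    swxx = (w * bx * bx).sum()
    swy = (w * by).sum()
    swxy = (w * bx * by).sum()
    det = sw * swxx - swx ** 2
    if det <= 0:
        raise DegenerateInstrumentError("exposure effects are collinear; Egger fit singular")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det

    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid ** 2) / (J - 2))
    scale = max(1.0, sigma2)
    se_intercept = math.sqrt(scale * swxx / det)
    se_slope = math.sqrt(scale * sw / det)

    slope_est = _estimate("egger_slope", J, slope, se_slope, w)
    intercept_est = _estimate("egger_intercept", J, intercept, se_intercept, w)
    return slope_est, intercept_est


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median at cumulative midpoint percentile 0.5."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    percentile = cum - w / 2.0
    return float(np.interp(0.5, percentile, v))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 42,
                    _min_snp: int = 3) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Consistent when instruments carrying over half the IVW weight are valid.
    The SE is the standard deviation of the estimate over ``n_boot``
    resamples drawing β*_Xj ~ N(β_Xj, se_Xj²) and β*_Yj ~ N(β_Yj, se_Yj²),
    with ratio weights recomputed per resample.
    """
    J = hset.n_snp
    if J < _min_snp:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= {_min_snp} instruments, got {J}")
    ratios, weights = _ratio_weights(hset)
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(hset.beta_exposure, hset.se_exposure, size=(n_boot, J))
    by_star = rng.normal(hset.beta_outcome, hset.se_outcome, size=(n_boot, J))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx = bx_star[b]
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)  # measure-zero guard
        boot[b] = _weighted_median(by_star[b] / bx, bx ** 2 / hset.se_outcome ** 2)
    se = float(boot.std(ddof=1))
    if se == 0:
        se = np.finfo(float).tiny ** 0.5
    return _estimate("weighted_median", J, beta, se, weights)


def _profile_loglik(theta: float, hset: HarmonizedSet) -> float:
    # exact profile over the nuisance true exposure effects ξ_j: plugging the
    # maximizing ξ_j*(θ) into the joint log-likelihood leaves
    # −Σ (β_Yj − θ β_Xj)² / (2(se_Yj² + θ² se_Xj²))
    var = hset.se_outcome ** 2 + theta ** 2 * hset.se_exposure ** 2
    resid = hset.beta_outcome - theta * hset.beta_exposure
    return float(-0.5 * np.sum(resid ** 2 / var))


def max_likelihood(hset: HarmonizedSet) -> MREstimate:
    """Maximum-likelihood estimate under the joint measurement-error model.

    Maximizes Σ_j [ −(β_Xj−ξ_j)²/(2se_Xj²) − (β_Yj−θξ_j)²/(2se_Yj²) ] over
    (θ, ξ_1..ξ_J).  The ξ_j are profiled out in closed form, leaving a
    one-dimensional optimization in θ initialized at the IVW estimate; the
    SE comes from the central-difference curvature of the profile
    log-likelihood at θ̂ (equal to the θθ block of the inverse observed
    information).  Accounts for measurement error in the SNP-exposure
    effects that the IVW weights ignore.
    """
    J = hset.n_snp
    if J == 0:
        raise InsufficientInstrumentsError("maximum likelihood needs >= 1 instrument")
    ratios, weights = _ratio_weights(hset)
    theta0 = float(np.sum(weights * ratios) / weights.sum())

    res = optimize.minimize(
        lambda t: -_profile_loglik(float(t[0]), hset), x0=[theta0],
        method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    if not np.isfinite(res.fun):
        raise ConvergenceError("likelihood optimization diverged",
                               diagnostics={"message": res.message, "x": res.x.tolist()})
    theta = float(res.x[0])

    # Newton polish on the 1-D profile to relative tolerance 1e-10
    converged = False
    for _ in range(50):
        h = 1e-6 * (1.0 + abs(theta))
        lp, lm, l0 = (_profile_loglik(theta + h, hset),
                      _profile_loglik(theta - h, hset),
                      _profile_loglik(theta, hset))
        grad = (lp - lm) / (2.0 * h)
        hess = (lp - 2.0 * l0 + lm) / h ** 2
        if hess >= 0:
            break  # not locally concave; keep quasi-Newton solution
        step = -grad / hess
        theta += step
        if abs(step) <= 1e-10 * (1.0 + abs(theta)):
            converged = True
            break
    if not converged and not res.success:
        raise ConvergenceError(
            "likelihood optimization did not converge",
            diagnostics={"theta": theta, "bfgs_message": res.message})

    h = 1e-5 * (1.0 + abs(theta))
    curvature = -(_profile_loglik(theta + h, hset) - 2.0 * _profile_loglik(theta, hset)
                  + _profile_loglik(theta - h, hset)) / h ** 2
    if curvature <= 0:
        raise ConvergenceError(
            "non-positive observed information at the optimum",
            diagnostics={"theta": theta, "curvature": curvature, "message": res.message})
    se = curvature ** -0.5
    return _estimate("max_likelihood", J, theta, se)
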