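"""Causal-effect estimators for summary-level two-sample MR.

Three estimators act on one harmonised instrument set, each returning the
causal log-OR per unit of exposure with a normal-theory Wald summary:

* **IVW** — the fixed-effects inverse-variance weighted ratio estimate

      beta_hat = sum_k X_k Y_k / sigma_Yk^2  /  sum_k X_k^2 / sigma_Yk^2
      se(beta_hat) = sqrt( 1 / sum_k X_k^2 / sigma_Yk^2 )

  equivalent to weighted least squares of Y on X through the origin with
  weights 1/sigma_Y^2; exposure-side error is ignored.

* **MLE** — maximum likelihood under the bivariate-normal measurement model

      X_k ~ N(xi_k, sigma_Xk^2),   Y_k ~ N(beta * xi_k, sigma_Yk^2)

  independent across and within SNPs, maximised over (xi_1..xi_K, beta).
  For fixed beta the xi_k maximisers are closed-form, so beta is found on
  the 1-D profile likelihood; SE(beta) comes from the analytic observed
  information of the full parameter vector (block inversion).  As all
  sigma_X -> 0 the MLE collapses to IVW.

* **MR-Egger** — weighted regression of Y on X *with* an intercept, each
  instrument oriented so X_k >= 0.  The slope is a pleiotropy-adjusted
  causal estimate; the intercept estimates the average direct (pleiotropic)
  effect of the instruments on the outcome and tests the exclusion
  restriction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import (CollinearityError, DomainError, EstimationError,
                         InsufficientDataError)
from .harmonize import HarmonizedInstrument

__all__ = [
    "MREstimate",
    "EggerResult",
    "InterceptEstimate",
    "MleFit",
    "wald_summary",
    "ivw_estimate",
    "mle_estimate",
    "egger_regression",
]


class WaldSummary(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class MREstimate:
    """A causal log-OR estimate with its normal-theory Wald summary."""

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    alpha: float = 0.05

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, n_snps: int,
                     alpha: float = 0.05) -> "MREstimate":
        if se > 0:
            w = wald_summary(beta, se, alpha)
        else:  # degenerate (exact-fit) case: point mass
            w = WaldSummary(float(np.exp(beta)), float(np.exp(beta)), float(np.exp(beta)), 0.0)
        return cls(method, float(beta), float(se), w.or_, w.ci_low, w.ci_high, w.p,
                   n_snps, alpha)

    def to_dict(self) -> dict:
        return {"method": self.method, "beta": self.beta, "se": self.se,
                "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "n_snps": self.n_snps, "alpha": self.alpha}


@dataclass(frozen=True)
class InterceptEstimate:
    """An additive-scale estimate (the Egger intercept) with CI and P."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p}


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: InterceptEstimate


@dataclass(frozen=True)
class MleFit:
    """Diagnostics of one bivariate-normal ML fit."""

    beta: float
    xi: tuple[float, ...]
    loglik: float
    converged: bool
    se_beta: float


def wald_summary(beta: float, se: float, alpha: float = 0.05) -> WaldSummary:
    """OR, (1-alpha) CI and two-sided normal P for a log-OR and its SE."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = min(1.0, 2.0 * stats.norm.sf(abs(beta) / se))
    with np.errstate(over="ignore"):  # huge SEs legitimately overflow to inf bounds
        return WaldSummary(float(np.exp(beta)), float(np.exp(beta - z * se)),
                           float(np.exp(beta + z * se)), float(p))


def _arrays(instruments: Iterable[HarmonizedInstrument]):
    ins = [i for i in instruments if i.included]
    if not ins:
        raise EstimationError("no non-excluded instruments")
    x = np.array([i.x for i in ins], dtype=float)
    sx = np.array([i.sigma_x for i in ins], dtype=float)
    y = np.array([i.y for i in ins], dtype=float)
    sy = np.array([i.sigma_y for i in ins], dtype=float)
    return x, sx, y, sy


def ivw_estimate(instruments: Sequence[HarmonizedInstrument], alpha: float = 0.05) -> MREstimate:
    """Fixed-effects inverse-variance weighted estimate.

    With a single instrument this reduces to the Wald ratio Y/X with
    SE sigma_Y/|X|.
    """
    x, _, y, sy = _arrays(instruments)
    if np.all(x == 0):
        raise EstimationError("degenerate instruments: every exposure effect is zero")
    w = sy ** -2.0
    denom = float(np.sum(x * x * w))
    beta = float(np.sum(x * y * w)) / denom
    se = float(np.sqrt(1.0 / denom))
    return MREstimate.from_beta_se("IVW", beta, se, len(x), alpha)


def _neg_profile_loglik(beta: float, x, sx2, y, sy2) -> float:
    xi = (x / sx2 + beta * y / sy2) / (1.0 / sx2 + beta * beta / sy2)
    return -_loglik(beta, xi, x, sx2, y, sy2)


def _loglik(beta: float, xi, x, sx2, y, sy2) -> float:
    return float(
        -0.5 * np.sum((x - xi) ** 2 / sx2 + np.log(2.0 * np.pi * sx2))
        - 0.5 * np.sum((y - beta * xi) ** 2 / sy2 + np.log(2.0 * np.pi * sy2))
    )


def mle_estimate(
    instruments: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
    return_fit: bool = False,
    max_restarts: int = 3,
):
    """Bivariate-normal maximum-likelihood estimate of the causal effect.

    Maximises the joint likelihood of the model ``X_k ~ N(xi_k, sigma_Xk^2)``,
    ``Y_k ~ N(beta xi_k, sigma_Yk^2)`` over (xi, beta), initialised at the
    IVW estimate with xi = X.  SE(beta) is the beta element of the inverse
    observed-information matrix at the optimum.  Returns the
    :class:`MREstimate`, or ``(MREstimate, MleFit)`` when ``return_fit``.
    """
    x, sx, y, sy = _arrays(instruments)
    sx2, sy2 = sx ** 2, sy ** 2
    b0 = ivw_estimate(instruments, alpha).beta
    rng = np.random.default_rng(0)  # jittered restarts only; deterministic
    best = None
    start = b0
    trace = "optimizer returned non-finite objective"
    for attempt in range(1 + max_restarts):
        try:
            res = optimize.minimize_scalar(
                _neg_profile_loglik, bracket=(start - 0.5, start + 0.5),
                args=(x, sx2, y, sy2), method="brent",
                options={"xtol": 1e-12, "maxiter": 500})
        except (RuntimeError, OverflowError) as exc:  # failed bracketing
            res = None
            trace = str(exc)
        if res is not None and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
            break
        start = b0 + 0.5 * rng.standard_normal()
    if best is None:
        raise EstimationError(f"MLE failed to converge after {max_restarts} restarts: {trace}")
    beta = float(best.x)
    xi = (x / sx2 + beta * y / sy2) / (1.0 / sx2 + beta * beta / sy2)
    # Observed information; the xi block is diagonal, so invert by blocks.
    i_bb = float(np.sum(xi ** 2 / sy2))
    i_xx = 1.0 / sx2 + beta ** 2 / sy2
    i_bx = -(y - 2.0 * beta * xi) / sy2
    profile_info = i_bb - float(np.sum(i_bx ** 2 / i_xx))
    if not profile_info > 0:
        raise EstimationError("observed information for beta is not positive definite")
    se = float(1.0 / np.sqrt(profile_info))
    est = MREstimate.from_beta_se("MLE", beta, se, len(x), alpha)
    if return_fit:
        fit = MleFit(beta=beta, xi=tuple(float(v) for v in xi),
                     loglik=_loglik(beta, xi, x, sx2, y, sy2),
                     converged=True, se_beta=se)
        return est, fit
    return est


def egger_regression(
    instruments: Sequence[HarmonizedInstrument],
    alpha: float = 0.05,
    use_t: bool = False,
) -> EggerResult:
    """MR-Egger weighted regression with an unconstrained intercept.

    Instruments are oriented so every X_k >= 0 (negating Y_k in tandem),
    then Y is regressed on X with weights 1/sigma_Y^2.  P values and CIs use
    the normal reference by default; ``use_t`` switches to a t reference
    with K-2 degrees of freedom.  The residual dispersion is estimated from
    the fit (statsmodels WLS default), so over-dispersion from balanced
    pleiotropy widens the intervals.
    """
    x, _, y, sy = _arrays(instruments)
    k = len(x)
    if k < 3:
        raise InsufficientDataError(f"MR-Egger needs >= 3 instruments, got {k}")
    sgn = np.where(x < 0, -1.0, 1.0)
    x, y = x * sgn, y * sgn
    if np.ptp(x) == 0:
        raise CollinearityError("all exposure effects equal; Egger design is collinear")
    design = sm.add_constant(x)
    fit = sm.WLS(y, design, weights=sy ** -2.0).fit()
    inter, slope = (float(v) for v in fit.params)
    se_inter, se_slope = (float(v) for v in fit.bse)
    df = k - 2
    if use_t:
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
        pval = lambda est, se: float(min(1.0, 2.0 * stats.t.sf(abs(est) / se, df)))
    else:
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
        pval = lambda est, se: float(min(1.0, 2.0 * stats.norm.sf(abs(est) / se)))

    if se_slope > 0:
        slope_est = MREstimate("Egger_slope", slope, se_slope,
                               float(np.exp(slope)),
                               float(np.exp(slope - crit * se_slope)),
                               float(np.exp(slope + crit * se_slope)),
                               pval(slope, se_slope), k, alpha)
    else:  # exact fit: zero residual dispersion
        slope_est = MREstimate.from_beta_se("Egger_slope", slope, 0.0, k, alpha)
    if se_inter > 0:
        intercept = InterceptEstimate(inter, se_inter, inter - crit * se_inter,
                                      inter + crit * se_inter, pval(inter, se_inter))
    else:
        intercept = InterceptEstimate(inter, 0.0, inter, inter, 0.0 if inter != 0 else 1.0)
    return EggerResult(slope=slope_est, intercept=intercept)
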