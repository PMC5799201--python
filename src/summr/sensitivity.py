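"""Stratified/exclusion sensitivity analyses, multiple testing, and MR power.

Sensitivity analyses re-run the estimators on subsets of the instrument set:
stratified analyses split the instruments by pathway (e.g. vitamin D
synthesis vs metabolism variants) to probe horizontal pleiotropy, and
exclusion analyses drop named SNPs (e.g. a variant associated with ancestry)
to probe population stratification.

Power calculations use the standard normal approximation for binary-outcome
MR: with N subjects of whom a fraction K are cases, and an instrument
explaining a fraction r2 of exposure variance, the detectable log-OR at a
given significance level and power is

    |log OR| = (z_{1-alpha/2} + z_{power}) / sqrt(N * r2 * K * (1-K))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .estimators import MREstimate, egger_regression, ivw_estimate, mle_estimate
from .exceptions import ConfigError, DomainError, EstimationError
from .harmonize import HarmonizedInstrument

__all__ = [
    "PowerSpec",
    "SensitivityResult",
    "stratified_analysis",
    "exclusion_analysis",
    "bonferroni_threshold",
    "detectable_or",
    "power_at_or",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to a binary-outcome MR power calculation.

    ``r2`` is the fraction of exposure variance explained by the instrument
    (default 0.02, i.e. about 2%); ``power`` may be omitted when the spec is
    used only with :func:`power_at_or`.
    """

    n_cases: int
    n_controls: int
    r2: float = 0.02
    alpha: float = 0.05
    power: float | None = None

    def __post_init__(self) -> None:
        if not (self.n_cases > 0 and self.n_controls > 0):
            raise DomainError("case and control counts must be positive")
        if not 0.0 < self.r2 < 1.0:
            raise DomainError(f"r2 must lie in (0, 1), got {self.r2}")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.power is not None and not 0.0 < self.power < 1.0:
            raise DomainError(f"power must lie in (0, 1), got {self.power}")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class SensitivityResult:
    """Estimates on one instrument subset, with deltas against the full set.

    ``estimates`` maps method name to an :class:`MREstimate` or None when the
    subset cannot support the method (e.g. Egger on 2 SNPs); ``comparison``
    maps method name to beta(subset) - beta(full set).
    """

    label: str
    snp_ids: tuple[str, ...]
    estimates: dict[str, MREstimate | None]
    comparison: dict[str, float | None]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "snp_ids": list(self.snp_ids),
            "estimates": {m: (e.to_dict() if e is not None else None)
                          for m, e in self.estimates.items()},
            "comparison": dict(self.comparison),
        }


_ESTIMATOR_DISPATCH = {
    "IVW": ivw_estimate,
    "MLE": mle_estimate,
}


def _estimate(method: str, instruments, alpha: float) -> MREstimate:
    if method == "Egger":
        return egger_regression(instruments, alpha).slope
    try:
        fn = _ESTIMATOR_DISPATCH[method]
    except KeyError:
        raise ConfigError(f"unknown estimation method {method!r}") from None
    return fn(instruments, alpha)


def _subset_result(
    label: str,
    subset: Sequence[HarmonizedInstrument],
    full: Mapping[str, MREstimate],
    methods: Sequence[str],
    alpha: float,
) -> SensitivityResult:
    estimates: dict[str, MREstimate | None] = {}
    comparison: dict[str, float | None] = {}
    for m in methods:
        if m == "Egger" and len(subset) < 3:
            estimates[m] = None
            comparison[m] = None
            continue
        est = _estimate(m, subset, alpha)
        estimates[m] = est
        comparison[m] = est.beta - full[m].beta if m in full else None
    return SensitivityResult(label=label, snp_ids=tuple(i.snp_id for i in subset),
                             estimates=estimates, comparison=comparison)


def stratified_analysis(
    instruments: Sequence[HarmonizedInstrument],
    strata: Mapping[str, str],
    methods: Sequence[str] = ("IVW", "MLE"),
    alpha: float = 0.05,
) -> list[SensitivityResult]:
    """Estimate within each stratum of the instrument set.

    ``strata`` maps every included SNP id to a stratum label.  Strata ending
    up with zero SNPs are skipped with a warning; Egger on a stratum of
    fewer than 3 SNPs is marked not-estimable (None) rather than an error.
    """
    ins = [i for i in instruments if i.included]
    missing = [i.snp_id for i in ins if i.snp_id not in strata]
    if missing:
        raise ConfigError(f"instruments without a stratum assignment: {missing}")
    full = {m: _estimate(m, ins, alpha) for m in methods
            if not (m == "Egger" and len(ins) < 3)}
    groups: dict[str, list[HarmonizedInstrument]] = {}
    for i in ins:
        groups.setdefault(strata[i.snp_id], []).append(i)
    results = []
    for label in sorted(groups):
        subset = groups[label]
        if not subset:
            warnings.warn(f"stratum {label!r} has no instruments; skipped", stacklevel=2)
            continue
        results.append(_subset_result(label, subset, full, methods, alpha))
    return results


def exclusion_analysis(
    instruments: Sequence[HarmonizedInstrument],
    drop: Sequence[str],
    methods: Sequence[str] = ("IVW", "MLE"),
    alpha: float = 0.05,
) -> SensitivityResult:
    """Re-estimate after dropping the named SNPs, recording deltas vs the full set."""
    ins = [i for i in instruments if i.included]
    ids = {i.snp_id for i in ins}
    unknown = [s for s in drop if s not in ids]
    if unknown:
        raise ConfigError(f"cannot drop SNPs absent from the instrument set: {unknown}")
    subset = [i for i in ins if i.snp_id not in set(drop)]
    if not subset:
        raise EstimationError("exclusion removes every instrument")
    full = {m: _estimate(m, ins, alpha) for m in methods
            if not (m == "Egger" and len(ins) < 3)}
    label = "drop:" + ",".join(drop) if drop else "full"
    return _subset_result(label, subset, full, methods, alpha)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha/m."""
    if m < 1:
        raise DomainError(f"number of tests must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / m


def detectable_or(spec: PowerSpec) -> tuple[float, float]:
    """Smallest detectable odds ratios (harmful, protective) at the target power."""
    if spec.power is None:
        raise ConfigError("PowerSpec.power is required for detectable_or")
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_p = stats.norm.ppf(spec.power)
    if z_a + z_p <= 0:
        raise DomainError(
            f"power {spec.power} is at or below the null rejection floor for alpha {spec.alpha}")
    k = spec.case_fraction
    denom = np.sqrt(spec.n_total * spec.r2 * k * (1.0 - k))
    log_or = float((z_a + z_p) / denom)
    return float(np.exp(log_or)), float(np.exp(-log_or))


def power_at_or(spec: PowerSpec, or_: float) -> float:
    """Power to detect a given odds ratio; the inverse of :func:`detectable_or`."""
    if not or_ > 0:
        raise DomainError(f"odds ratio must be > 0, got {or_}")
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    k = spec.case_fraction
    denom = np.sqrt(spec.n_total * spec.r2 * k * (1.0 - k))
    return float(stats.norm.cdf(denom * abs(np.log(or_)) - z_a))
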