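"""Synthetic multi-cohort two-sample MR datasets with known ground truth.

The generator works at the summary level — exactly the data model the
estimators assume.  Per SNP k a true exposure effect xi_k is drawn (or fixed
from a template instrument set), the *observed* exposure effect is
X_k ~ N(xi_k, sigma_Xk^2), and per outcome cohort c

    Y_kc ~ N(beta * xi_k + alpha_k, sigma_Ykc^2)

where alpha_k is a per-SNP direct (pleiotropic) effect on the outcome and
the outcome SE follows the standard log-OR approximation

    sigma_Ykc = 1 / sqrt(2 p_k (1 - p_k) N_c K_c (1 - K_c))

with p_k the effect-allele frequency, N_c the cohort size and K_c its case
fraction.  One exposure table is shared by all cohorts within a replicate,
as in real two-sample MR where a single exposure GWAS serves every outcome
cohort.  Allele labels (optionally palindromic) and reporting orientation
are scrambled so the harmonisation stage is genuinely exercised, and every
draw is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate
from .exceptions import ConfigError, VocabularyError
from .summary_io import (ExposureAssociation, OutcomeAssociation, Pathway,
                         Subtype, builtin_sunlight_instruments,
                         write_exposure_table, write_outcome_table)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "scenario_presets",
    "score_estimates",
    "PAPER_COHORTS",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                         ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Eight glioma GWAS cohorts; the published totals (12,488 cases / 18,169
# controls) split evenly, remainders to the first cohorts.
_COHORT_LABELS = ("FRE", "GER", "GICC", "MDA", "NIH", "UCSF-Mayo", "UCSF", "UK")


def _split_counts(total: int, n: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


PAPER_COHORTS: tuple[tuple[str, int, int], ...] = tuple(
    (label, c, k) for label, c, k in zip(
        _COHORT_LABELS, _split_counts(12488, 8), _split_counts(18169, 8))
)

# Fixed realistic effect-allele frequencies for the template instrument set,
# chosen away from 0.5 so the palindromic rs6013897 is frequency-resolvable.
_TEMPLATE_EAFS = {
    "rs2282679": 0.28,
    "rs10741657": 0.60,
    "rs12785878": 0.75,
    "rs6013897": 0.80,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth and sampling conditions for one simulated dataset."""

    n_snps: int = 4
    true_beta: float = 0.0
    xi_range: tuple[float, float] = (-0.06, -0.02)
    sigma_x_range: tuple[float, float] = (0.012, 0.015)
    cohorts: tuple[tuple[str, int, int], ...] = PAPER_COHORTS
    subtypes: tuple[str, ...] = (Subtype.ALL_GLIOMA.value,)
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 0.25
    eaf_range: tuple[float, float] = (0.1, 0.9)
    scramble_orientation: bool = True
    template: tuple[ExposureAssociation, ...] | None = None
    template_eafs: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for name in ("xi_range", "sigma_x_range", "eaf_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigError(f"{name} is degenerate: ({lo}, {hi})")
        if not self.sigma_x_range[0] > 0:
            raise ConfigError("sigma_x_range must be strictly positive")
        if not (0.0 < self.eaf_range[0] and self.eaf_range[1] < 1.0):
            raise ConfigError("eaf_range must lie inside (0, 1)")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ConfigError("palindromic_fraction must lie in [0, 1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if not self.cohorts:
            raise ConfigError("at least one cohort is required")
        for label, n_cases, n_controls in self.cohorts:
            if n_cases <= 0 or n_controls <= 0:
                raise ConfigError(f"cohort {label}: counts must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated two-sample MR dataset plus the truth that generated it."""

    exposures: tuple[ExposureAssociation, ...]
    outcomes: tuple[OutcomeAssociation, ...]
    truth: dict

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write exposure and outcome tables as TSV; returns their paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        exp_path = directory / "exposure.tsv"
        out_path = directory / "outcome.tsv"
        write_exposure_table(list(self.exposures), exp_path)
        write_outcome_table(list(self.outcomes), out_path)
        return exp_path, out_path


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Draw one dataset under ``config`` (``seed`` overrides ``config.seed``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if config.template is not None:
        tmpl = list(config.template)
        n = len(tmpl)
        snp_ids = [t.snp_id for t in tmpl]
        xi = np.array([t.beta_exposure for t in tmpl])
        sx = np.array([t.se_exposure for t in tmpl])
        eafs_map = dict(config.template_eafs or {})
        eaf = np.array([
            eafs_map.get(t.snp_id, t.eaf if t.eaf is not None else 0.5) for t in tmpl
        ])
        alleles = [(t.effect_allele, t.other_allele) for t in tmpl]
        meta = [(t.chrom, t.position, t.locus, t.pathway) for t in tmpl]
    else:
        n = config.n_snps
        snp_ids = [f"rsSIM{i + 1:04d}" for i in range(n)]
        xi = rng.uniform(*config.xi_range, size=n)
        sx = rng.uniform(*config.sigma_x_range, size=n)
        eaf = rng.uniform(*config.eaf_range, size=n)
        pal = rng.random(n) < config.palindromic_fraction
        alleles = []
        for k in range(n):
            pool = _PALINDROMIC_PAIRS if pal[k] else _NONPALINDROMIC_PAIRS
            alleles.append(pool[rng.integers(len(pool))])
        meta = [(str(1 + k % 22), 1_000_000 + 10_000 * k, "", Pathway.UNKNOWN)
                for k in range(n)]

    x_obs = rng.normal(xi, sx)
    if config.pleiotropy == "none":
        alpha_k = np.zeros(n)
    elif config.pleiotropy == "balanced":
        alpha_k = rng.normal(0.0, config.pleiotropy_sd, size=n)
    else:
        alpha_k = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n)

    exposures = tuple(
        ExposureAssociation(
            snp_id=snp_ids[k], chrom=meta[k][0], position=meta[k][1],
            effect_allele=alleles[k][0], other_allele=alleles[k][1],
            beta_exposure=float(x_obs[k]), se_exposure=float(sx[k]),
            f_stat=float((x_obs[k] / sx[k]) ** 2) or None,
            locus=meta[k][2], pathway=meta[k][3], eaf=float(eaf[k]),
        )
        for k in range(n)
    )

    # Per-SNP reporting orientation of the outcome GWAS, constant across
    # cohorts (one outcome meta-analysis reports each SNP once per cohort
    # with a single orientation convention).
    if config.scramble_orientation:
        swap = rng.random(n) < 0.5
        strand = (rng.random(n) < 0.3) & np.array(
            [not _is_pal(a, b) for a, b in alleles])
    else:
        swap = np.zeros(n, dtype=bool)
        strand = np.zeros(n, dtype=bool)

    outcomes: list[OutcomeAssociation] = []
    for subtype in config.subtypes:
        for label, n_cases, n_controls in config.cohorts:
            n_tot = n_cases + n_controls
            frac = n_cases / n_tot
            for k in range(n):
                se_y = 1.0 / math.sqrt(2.0 * eaf[k] * (1.0 - eaf[k])
                                       * n_tot * frac * (1.0 - frac))
                y = rng.normal(config.true_beta * xi[k] + alpha_k[k], se_y)
                ea, oa = alleles[k]
                y_rep, eaf_rep = y, float(eaf[k])
                if swap[k]:
                    ea, oa = oa, ea
                    y_rep, eaf_rep = -y, 1.0 - eaf_rep
                if strand[k]:
                    ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
                outcomes.append(OutcomeAssociation(
                    snp_id=snp_ids[k], effect_allele=ea, other_allele=oa,
                    beta_outcome=float(y_rep), se_outcome=float(se_y),
                    cohort=label, subtype=subtype, eaf=eaf_rep,
                ))

    truth = {
        "true_beta": config.true_beta,
        "xi": [float(v) for v in xi],
        "alpha": [float(v) for v in alpha_k],
        "snp_ids": snp_ids,
        "swapped": [bool(v) for v in swap],
        "strand_flipped": [bool(v) for v in strand],
    }
    return SimulatedDataset(exposures=exposures, outcomes=tuple(outcomes), truth=truth)


def _is_pal(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def scenario_presets(name: str) -> SimulationConfig:
    """Named, fully specified simulation scenarios.

    * ``null`` — 4 instruments shaped like the 25(OH)D set, 8 cohorts at the
      published case/control totals, no causal effect, no pleiotropy.
    * ``causal`` — as ``null`` with true beta = log(0.62) (the published
      GBM-scale effect magnitude).
    * ``paper_like`` — the four real instrument SNPs (ids, alleles, effects
      and SEs) with fixed realistic allele frequencies, true beta =
      log(0.62), 8 cohorts at the published totals.
    * ``balanced_pleiotropy`` / ``directional_pleiotropy`` — 10 instruments
      with a spread of strengths, one combined cohort, per-SNP direct
      effects of sd 0.02 centred at 0 (balanced) or 0.03 (directional).
    """
    combined = (("ALL", 12488, 18169),)
    if name == "null":
        return SimulationConfig(true_beta=0.0)
    if name == "causal":
        return SimulationConfig(true_beta=math.log(0.62))
    if name == "paper_like":
        return SimulationConfig(
            n_snps=4, true_beta=math.log(0.62),
            template=tuple(builtin_sunlight_instruments()),
            template_eafs=dict(_TEMPLATE_EAFS),
        )
    if name == "balanced_pleiotropy":
        return SimulationConfig(
            n_snps=10, true_beta=0.0, xi_range=(-0.10, -0.02),
            cohorts=combined, pleiotropy="balanced", pleiotropy_sd=0.02,
            palindromic_fraction=0.0,
        )
    if name == "directional_pleiotropy":
        return SimulationConfig(
            n_snps=10, true_beta=0.0, xi_range=(-0.10, -0.02),
            cohorts=combined, pleiotropy="directional",
            pleiotropy_mean=0.03, pleiotropy_sd=0.02,
            palindromic_fraction=0.0,
        )
    raise VocabularyError(f"unknown scenario {name!r}; known: null, causal, "
                          "paper_like, balanced_pleiotropy, directional_pleiotropy")


def score_estimates(
    truth: Mapping | float,
    estimates: Mapping[str, Sequence[MREstimate]] | Sequence[MREstimate],
) -> pd.DataFrame:
    """Score replicate estimates against the generating truth.

    Returns one row per method with bias, RMSE, empirical SE, 95% CI
    coverage of the true effect, and the rejection rate of the no-effect
    null at each estimate's own alpha (type-I error under a null truth,
    power otherwise).
    """
    true_beta = float(truth["true_beta"]) if isinstance(truth, Mapping) else float(truth)
    if not isinstance(estimates, Mapping):
        groups: dict[str, list[MREstimate]] = {}
        for e in estimates:
            groups.setdefault(e.method, []).append(e)
    else:
        groups = {m: list(v) for m, v in estimates.items()}
    rows = []
    for method in sorted(groups):
        ests = groups[method]
        b = np.array([e.beta for e in ests])
        lo = np.log([e.ci_low for e in ests])
        hi = np.log([e.ci_high for e in ests])
        rej = np.array([e.p < e.alpha for e in ests])
        rows.append({
            "method": method,
            "n_reps": len(ests),
            "mean_beta": float(np.mean(b)),
            "bias": float(np.mean(b) - true_beta),
            "rmse": float(np.sqrt(np.mean((b - true_beta) ** 2))),
            "empirical_se": float(np.std(b, ddof=1)) if len(ests) > 1 else 0.0,
            "coverage": float(np.mean((lo <= true_beta) & (true_beta <= hi))),
            "rejection_rate": float(np.mean(rej)),
        })
    return pd.DataFrame(rows).set_index("method")
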