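"""End-to-end analysis orchestration: read -> harmonise -> estimate -> pool -> report.

A :class:`RunConfig` (built in code or loaded from YAML) names the inputs —
either summary-statistic tables or a simulation scenario — and the analysis
plan: subtypes, estimators, sensitivity blocks and power specs.
:func:`run_analysis` executes the full pipeline and returns an
:class:`~summr.summary_io.AnalysisReport`; with an output directory set, the
report is also written as JSON (full precision) and TSV (display precision,
mirroring the published table layout) together with the harmonisation log.

The pipeline order follows the two-sample design: the causal effect is
estimated within each outcome cohort first, and the cohort-level estimates
are then pooled by fixed-effect meta-analysis.  An alternative order (pool
the per-SNP outcome effects across cohorts, then estimate once) is available
behind ``pool_snps_first`` for comparison and is off by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .estimators import egger_regression
from .exceptions import ConfigError, EstimationError, SummrError
from .harmonize import (check_ld_independence, harmonization_log,
                        harmonize_dataset, orient_increasing)
from .meta import fixed_effect_meta, forest_data, pool_fixed
from .sensitivity import (PowerSpec, bonferroni_threshold, detectable_or,
                          exclusion_analysis, stratified_analysis)
from .simulate import scenario_presets, simulate_dataset
from .summary_io import (AnalysisReport, Pathway, Subtype,
                         builtin_sunlight_instruments, group_outcomes,
                         read_exposure_table, read_outcome_table,
                         write_report)
from .sensitivity import _estimate  # shared method dispatch

logger = logging.getLogger("summr")

__all__ = ["RunConfig", "validate_config", "run_analysis"]

_KNOWN_METHODS = ("IVW", "MLE", "Egger")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see field comments for semantics."""

    scenario: str | None = None            # simulation scenario name, or None
    exposure_path: str | None = None       # TSV inputs when scenario is None
    outcome_path: str | None = None
    exposure_dialect: dict | None = None
    outcome_dialect: dict | None = None
    use_builtin_instruments: bool = False  # exposure side from the built-in set
    subtypes: tuple[str, ...] = (Subtype.ALL_GLIOMA.value,)
    methods: tuple[str, ...] = ("IVW", "MLE", "Egger")
    meta: bool = True
    pool_snps_first: bool = False
    strata: dict[str, str] | str | None = None  # snp -> stratum map, or "pathway" to use tags
    exclusions: tuple[str, ...] = ()
    power: tuple[dict, ...] = ()           # dicts of PowerSpec fields (+ label)
    alpha: float = 0.05
    bonferroni_m: int = 3
    ld_matrix_path: str | None = None
    ld_threshold: float = 0.001
    palindromic_window: float = 0.08
    egger_t: bool = False
    seed: int = 0
    output_dir: str | None = None
    keep_going: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subtypes", "methods", "exclusions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "power" in raw and raw["power"] is not None:
            raw["power"] = tuple(raw["power"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("subtypes", "methods", "exclusions", "power"):
            d[key] = list(d[key]) if d[key] is not None else None
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    if config.scenario is None and not config.use_builtin_instruments and config.exposure_path is None:
        problems.append("exposure_path: set a path, a scenario, or use_builtin_instruments")
    if config.scenario is None and config.outcome_path is None:
        problems.append("outcome_path: set a path or choose a scenario")
    if config.scenario is not None and config.outcome_path is not None:
        problems.append("scenario and outcome_path are mutually exclusive")
    for path_field in ("exposure_path", "outcome_path", "ld_matrix_path"):
        p = getattr(config, path_field)
        if p is not None and not Path(p).exists():
            problems.append(f"{path_field}: file not found: {p}")
    if not config.methods:
        problems.append("methods: at least one estimation method is required")
    for m in config.methods:
        if m not in _KNOWN_METHODS:
            problems.append(f"methods: unknown method {m!r} (known: {_KNOWN_METHODS})")
    if not config.subtypes:
        problems.append("subtypes: at least one subtype is required")
    if not 0.0 < config.alpha < 1.0:
        problems.append(f"alpha: must lie in (0, 1), got {config.alpha}")
    if config.bonferroni_m < 1:
        problems.append(f"bonferroni_m: must be >= 1, got {config.bonferroni_m}")
    if not 0.0 <= config.palindromic_window < 0.5:
        problems.append("palindromic_window: must lie in [0, 0.5)")
    for i, spec in enumerate(config.power):
        try:
            PowerSpec(**{k: v for k, v in spec.items() if k != "label"})
        except (TypeError, SummrError) as exc:
            problems.append(f"power[{i}]: {exc}")
    return problems


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sim_cfg = scenario_presets(config.scenario)
        ds = simulate_dataset(sim_cfg, seed=config.seed)
        return list(ds.exposures), list(ds.outcomes), {"scenario": config.scenario}
    if config.use_builtin_instruments:
        exposures = builtin_sunlight_instruments()
        inputs = {"exposure": "builtin_sunlight_instruments"}
    else:
        exposures = read_exposure_table(config.exposure_path, config.exposure_dialect)
        inputs = {"exposure": str(config.exposure_path)}
    outcomes = read_outcome_table(config.outcome_path, config.outcome_dialect)
    inputs["outcome"] = str(config.outcome_path)
    return exposures, outcomes, inputs


def _pool_outcomes_across_cohorts(outcome_groups, subtype):
    """Fixed-effect pool of per-SNP outcome effects across cohorts (optional order)."""
    per_snp: dict[str, list] = {}
    for (cohort, st), recs in outcome_groups.items():
        if st != subtype:
            continue
        for r in recs:
            per_snp.setdefault(r.snp_id, []).append(r)
    pooled = []
    for snp_id, recs in per_snp.items():
        beta, se, _ = pool_fixed([r.beta_outcome for r in recs],
                                 [r.se_outcome for r in recs])
        pooled.append(dataclasses.replace(recs[0], beta_outcome=beta, se_outcome=se,
                                          cohort="POOLED"))
    return pooled


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full pipeline described by ``config``.

    Raises :class:`ConfigError` before any computation if the config does not
    validate; estimation failures abort the run unless ``keep_going`` is set,
    in which case the failing subtype is recorded in the report provenance.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))

    exposures, outcomes, inputs = _load_inputs(config)
    logger.info("loaded %d exposure SNPs, %d outcome records", len(exposures), len(outcomes))

    report = AnalysisReport()
    report.provenance = {
        "inputs": inputs,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "failures": [],
    }

    snp_ids = [e.snp_id for e in exposures]
    if config.ld_matrix_path is not None:
        mat = pd.read_csv(config.ld_matrix_path, sep="\t", index_col=0)
        ld = check_ld_independence(snp_ids, mat, config.ld_threshold)
        report.ld = [{"snp_a": r.snp_a, "snp_b": r.snp_b, "r2": r.r2,
                      "status": r.status} for r in ld]
        linked = [r for r in ld if r.independent is False]
        if linked:
            logger.warning("%d SNP pairs exceed the LD threshold", len(linked))

    outcome_groups = group_outcomes(outcomes)
    subtype_values = [Subtype(s) for s in config.subtypes]
    all_log_rows: list[dict] = []

    for subtype in subtype_values:
        cohorts = sorted({c for (c, st) in outcome_groups if st == subtype})
        if not cohorts:
            msg = f"no outcome records for subtype {subtype.value}"
            if config.keep_going:
                report.provenance["failures"].append(msg)
                logger.warning(msg)
                continue
            raise EstimationError(msg)
        try:
            _analyse_subtype(config, report, exposures, outcome_groups, subtype,
                             cohorts, all_log_rows)
        except SummrError as exc:
            if config.keep_going:
                report.provenance["failures"].append(f"{subtype.value}: {exc}")
                logger.warning("subtype %s failed: %s", subtype.value, exc)
            else:
                raise

    report.harmonization_log = all_log_rows
    report.bonferroni = {
        "alpha": config.alpha,
        "m": config.bonferroni_m,
        "threshold": bonferroni_threshold(config.alpha, config.bonferroni_m),
    }
    if config.power:
        rows = []
        for spec in config.power:
            label = spec.get("label", "")
            ps = PowerSpec(**{k: v for k, v in spec.items() if k != "label"})
            harmful, protective = detectable_or(ps)
            rows.append({"label": label, "n_cases": ps.n_cases,
                         "n_controls": ps.n_controls, "r2": ps.r2,
                         "alpha": ps.alpha, "power": ps.power,
                         "or_harmful": harmful, "or_protective": protective})
        report.power = rows

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json", "json")
        write_report(report, out / "report.tsv", "tsv")
        pd.DataFrame(all_log_rows).to_csv(out / "harmonization_log.tsv", sep="\t", index=False)
        logger.info("report written to %s", out)
    return report


def _analyse_subtype(config, report, exposures, outcome_groups, subtype, cohorts,
                     all_log_rows):
    # Harmonise per cohort; instruments are re-expressed per unit *increase*
    # in the exposure so OR < 1 reads as protective.
    per_cohort_instruments = {}
    for cohort in cohorts:
        recs = outcome_groups[(cohort, subtype)]
        pairs = harmonize_dataset(exposures, recs, config.palindromic_window)
        log = harmonization_log(pairs)
        all_log_rows.extend(log.to_dict("records"))
        included = [p for p in pairs if p.included]
        logger.info("%s/%s: %d/%d instruments after harmonisation",
                    cohort, subtype.value, len(included), len(pairs))
        per_cohort_instruments[cohort] = orient_increasing(pairs)

    if config.pool_snps_first:
        pooled_recs = _pool_outcomes_across_cohorts(outcome_groups, subtype)
        pooled_pairs = orient_increasing(
            harmonize_dataset(exposures, pooled_recs, config.palindromic_window))
        per_cohort_instruments = {"POOLED": pooled_pairs}
        cohorts = ["POOLED"]

    for method in config.methods:
        if method == "Egger":
            _egger_subtype(config, report, per_cohort_instruments, cohorts, subtype)
            continue
        per_cohort = []
        for cohort in cohorts:
            est = _estimate(method, per_cohort_instruments[cohort], config.alpha)
            per_cohort.append((cohort, est))
        if config.meta and len(per_cohort) > 1:
            meta = fixed_effect_meta(per_cohort, config.alpha, subtype=subtype.value)
            pooled = meta.pooled
            fd = forest_data(meta)
            for row in fd.to_dict("records"):
                report.forest.append({
                    "subtype": subtype.value, "method": method,
                    "cohort": row["cohort"], "or": row["or"],
                    "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "weight": None if np.isnan(row["weight"]) else row["weight"],
                })
            logger.info("%s/%s pooled over %d cohorts (Q=%.2f, I2=%.2f)",
                        method, subtype.value, len(cohorts), meta.q, meta.i2)
        else:
            pooled = per_cohort[0][1]
        report.estimates.append({
            "subtype": subtype.value, "method": method, "n_snps": pooled.n_snps,
            "beta": pooled.beta, "se": pooled.se, "or": pooled.or_,
            "ci_low": pooled.ci_low, "ci_high": pooled.ci_high, "p": pooled.p,
        })

    _sensitivity_subtype(config, report, per_cohort_instruments, cohorts, subtype)


def _egger_subtype(config, report, per_cohort_instruments, cohorts, subtype):
    slopes, inters = [], []
    for cohort in cohorts:
        res = egger_regression(per_cohort_instruments[cohort], config.alpha,
                               use_t=config.egger_t)
        slopes.append((cohort, res.slope))
        inters.append((res.intercept.estimate, res.intercept.se))
    if config.meta and len(cohorts) > 1:
        meta = fixed_effect_meta(slopes, config.alpha, subtype=subtype.value)
        slope = meta.pooled
        ib, ise, _ = pool_fixed([b for b, _ in inters], [s for _, s in inters])
    else:
        slope = slopes[0][1]
        ib, ise = inters[0]
    crit = float(stats.norm.ppf(1.0 - config.alpha / 2.0))
    ip = float(min(1.0, 2.0 * stats.norm.sf(abs(ib) / ise))) if ise > 0 else (1.0 if ib == 0 else 0.0)
    report.estimates.append({
        "subtype": subtype.value, "method": "Egger", "n_snps": slope.n_snps,
        "beta": slope.beta, "se": slope.se, "or": slope.or_,
        "ci_low": slope.ci_low, "ci_high": slope.ci_high, "p": slope.p,
    })
    report.egger.append({
        "subtype": subtype.value,
        "slope": {"estimate": slope.beta, "se": slope.se,
                  "ci_low": slope.beta - crit * slope.se,
                  "ci_high": slope.beta + crit * slope.se, "p": slope.p},
        "intercept": {"estimate": ib, "se": ise, "ci_low": ib - crit * ise,
                      "ci_high": ib + crit * ise, "p": ip},
    })


def _sensitivity_subtype(config, report, per_cohort_instruments, cohorts, subtype):
    methods = tuple(m for m in config.methods if m != "Egger")
    if not methods:
        return
    strata_map = config.strata
    if strata_map == "pathway":
        strata_map = None
        tagged = {}
        for cohort in cohorts:
            for ins in per_cohort_instruments[cohort]:
                if ins.included and ins.pathway is not Pathway.UNKNOWN:
                    tagged[ins.snp_id] = ins.pathway.value
        if tagged:
            strata_map = tagged
    rows = []
    if strata_map:
        rows.extend(_pooled_sensitivity(
            config, per_cohort_instruments, cohorts, subtype, methods,
            kind="stratified", strata=strata_map))
    for snp in config.exclusions:
        rows.extend(_pooled_sensitivity(
            config, per_cohort_instruments, cohorts, subtype, methods,
            kind="exclusion", drop=(snp,)))
    if rows:
        report.sensitivity = (report.sensitivity or []) + rows


def _pooled_sensitivity(config, per_cohort_instruments, cohorts, subtype, methods,
                        kind, strata=None, drop=None):
    """Run a sensitivity analysis per cohort and pool the subset estimates."""
    per_label: dict[str, dict[str, list]] = {}
    snp_ids: dict[str, tuple] = {}
    deltas: dict[str, dict[str, list]] = {}
    for cohort in cohorts:
        ins = per_cohort_instruments[cohort]
        if kind == "stratified":
            results = stratified_analysis(ins, strata, methods, config.alpha)
        else:
            results = [exclusion_analysis(ins, list(drop), methods, config.alpha)]
        for res in results:
            snp_ids.setdefault(res.label, res.snp_ids)
            for m, est in res.estimates.items():
                if est is None:
                    continue
                per_label.setdefault(res.label, {}).setdefault(m, []).append((cohort, est))
                deltas.setdefault(res.label, {}).setdefault(m, []).append(res.comparison[m])
    rows = []
    for label in sorted(per_label):
        estimates, comparison = {}, {}
        for m in methods:
            comps = per_label[label].get(m)
            if not comps:
                estimates[m] = None
                comparison[m] = None
                continue
            pooled = (fixed_effect_meta(comps, config.alpha).pooled
                      if len(comps) > 1 else comps[0][1])
            estimates[m] = pooled.to_dict()
            dl = [d for d in deltas[label][m] if d is not None]
            comparison[m] = float(np.mean(dl)) if dl else None
        rows.append({
            "subtype": subtype.value, "analysis": kind, "label": label,
            "snp_ids": list(snp_ids[label]),
            "estimates": estimates, "comparison": comparison,
        })
    return rows
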