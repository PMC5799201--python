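"""Reading and writing GWAS summary-statistic tables and analysis reports.

Two-sample Mendelian randomisation needs only two kinds of input: per-SNP
associations with the exposure (here serum 25-hydroxyvitamin D, 25(OH)D) and
per-SNP associations with the outcome (glioma risk, as log odds ratios), each
with a standard error and allele metadata.  This module defines the record
types for both sides, tab-separated readers/writers with a configurable
column dialect, the built-in four-SNP 25(OH)D instrument set, and the
:class:`AnalysisReport` container the pipeline emits.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import DuplicateSnpError, FormatError, VocabularyError

__all__ = [
    "Pathway",
    "Subtype",
    "ExposureAssociation",
    "OutcomeAssociation",
    "AnalysisReport",
    "DEFAULT_EXPOSURE_DIALECT",
    "DEFAULT_OUTCOME_DIALECT",
    "read_exposure_table",
    "read_outcome_table",
    "write_exposure_table",
    "write_outcome_table",
    "builtin_sunlight_instruments",
    "write_report",
    "read_report",
]

_VALID_ALLELES = frozenset("ACGT")


class Pathway(str, enum.Enum):
    """Vitamin D pathway arm an instrument acts through."""

    SYNTHESIS = "synthesis"
    METABOLISM = "metabolism"
    UNKNOWN = "unknown"


class Subtype(str, enum.Enum):
    """Glioma outcome classification."""

    ALL_GLIOMA = "all_glioma"
    GBM = "GBM"
    NON_GBM = "non_GBM"


def _check_allele(a: str, what: str) -> str:
    a = str(a).upper()
    if a not in _VALID_ALLELES:
        raise FormatError(f"{what} must be one of A/C/G/T, got {a!r}")
    return a


@dataclass(frozen=True)
class ExposureAssociation:
    """One instrument SNP's per-allele association with 25(OH)D level.

    ``beta_exposure`` is on the scale the source study printed (per effect
    allele); by convention the effect allele is the 25(OH)D-*decreasing*
    allele, so the built-in instruments all carry negative betas.
    """

    snp_id: str
    chrom: str
    position: int
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    f_stat: float | None = None
    locus: str = ""
    pathway: Pathway = Pathway.UNKNOWN
    eaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        object.__setattr__(self, "pathway", Pathway(self.pathway))
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se_exposure > 0:
            raise FormatError(f"{self.snp_id}: se_exposure must be > 0, got {self.se_exposure}")
        if self.f_stat is not None and not self.f_stat > 0:
            raise FormatError(f"{self.snp_id}: f_stat must be > 0 when present")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise FormatError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")


@dataclass(frozen=True)
class OutcomeAssociation:
    """One SNP's log-OR association with an outcome in one cohort."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_outcome: float
    se_outcome: float
    cohort: str
    subtype: Subtype = Subtype.ALL_GLIOMA
    eaf: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        try:
            object.__setattr__(self, "subtype", Subtype(self.subtype))
        except ValueError as exc:
            raise VocabularyError(f"{self.snp_id}: unknown subtype {self.subtype!r}") from exc
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se_outcome > 0:
            raise FormatError(f"{self.snp_id}: se_outcome must be > 0, got {self.se_outcome}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise FormatError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not self.cohort:
            raise FormatError(f"{self.snp_id}: cohort label must be non-empty")


# Canonical field -> default column header.  A "dialect" is any mapping that
# overrides entries of these; sources (SUNLIGHT, CaMOS, GICC exports) differ
# only in their headers, never in content.
DEFAULT_EXPOSURE_DIALECT: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta_exposure": "beta",
    "se_exposure": "se",
    "f_stat": "f_stat",
    "locus": "locus",
    "pathway": "pathway",
    "eaf": "eaf",
}

DEFAULT_OUTCOME_DIALECT: dict[str, str] = {
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta_outcome": "beta",
    "se_outcome": "se",
    "cohort": "cohort",
    "subtype": "subtype",
    "eaf": "eaf",
}

_EXPOSURE_MANDATORY = ("snp_id", "chrom", "position", "effect_allele", "other_allele",
                       "beta_exposure", "se_exposure")
_OUTCOME_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta_outcome", "se_outcome")


def _resolve_dialect(base: Mapping[str, str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(base)
    if dialect:
        unknown = set(dialect) - set(base)
        if unknown:
            raise FormatError(f"dialect maps unknown fields: {sorted(unknown)}")
        cols.update(dialect)
    return cols


def _opt(row: pd.Series, col: str | None):
    if col is None or col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_exposure_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[ExposureAssociation]:
    """Read a tab-separated exposure (SNP -> 25(OH)D) association table.

    Parameters
    ----------
    path
        TSV file with one row per SNP.
    dialect
        Optional mapping from canonical field names (keys of
        :data:`DEFAULT_EXPOSURE_DIALECT`) to the file's column headers.

    Raises
    ------
    FormatError
        A mandatory column is missing (the error names it) or a row violates
        a field invariant (the error names the row).
    DuplicateSnpError
        The same rsID occurs twice.
    """
    cols = _resolve_dialect(DEFAULT_EXPOSURE_DIALECT, dialect)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={cols["snp_id"]: str, cols["chrom"]: str})
    for f in _EXPOSURE_MANDATORY:
        if cols[f] not in df.columns:
            raise FormatError(f"exposure table {path}: missing mandatory column {cols[f]!r} (field {f})")
    records: list[ExposureAssociation] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        try:
            rec = ExposureAssociation(
                snp_id=str(row[cols["snp_id"]]),
                chrom=str(row[cols["chrom"]]),
                position=int(row[cols["position"]]),
                effect_allele=row[cols["effect_allele"]],
                other_allele=row[cols["other_allele"]],
                beta_exposure=float(row[cols["beta_exposure"]]),
                se_exposure=float(row[cols["se_exposure"]]),
                f_stat=(None if _opt(row, cols.get("f_stat")) is None else float(row[cols["f_stat"]])),
                locus=str(_opt(row, cols.get("locus")) or ""),
                pathway=Pathway(str(_opt(row, cols.get("pathway")) or "unknown")),
                eaf=(None if _opt(row, cols.get("eaf")) is None else float(row[cols["eaf"]])),
            )
        except FormatError as exc:
            raise FormatError(f"exposure table {path}, row {i + 1}: {exc}") from exc
        if rec.snp_id in seen:
            raise DuplicateSnpError(f"exposure table {path}: duplicate snp_id {rec.snp_id}")
        seen.add(rec.snp_id)
        records.append(rec)
    return records


def read_outcome_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    cohort: str | None = None,
    subtype: str | Subtype | None = None,
) -> list[OutcomeAssociation]:
    """Read a tab-separated outcome (SNP -> glioma log-OR) association table.

    ``cohort`` and ``subtype`` may be table columns or supplied here as
    constants applied to every row (a constant overrides a missing column,
    not a present one).
    """
    cols = _resolve_dialect(DEFAULT_OUTCOME_DIALECT, dialect)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={cols["snp_id"]: str})
    for f in _OUTCOME_MANDATORY:
        if cols[f] not in df.columns:
            raise FormatError(f"outcome table {path}: missing mandatory column {cols[f]!r} (field {f})")
    has_cohort = cols["cohort"] in df.columns
    has_subtype = cols["subtype"] in df.columns
    if not has_cohort and cohort is None:
        raise FormatError(f"outcome table {path}: no cohort column and no cohort constant supplied")
    if not has_subtype and subtype is None:
        raise FormatError(f"outcome table {path}: no subtype column and no subtype constant supplied")
    records: list[OutcomeAssociation] = []
    for i, row in df.iterrows():
        try:
            rec = OutcomeAssociation(
                snp_id=str(row[cols["snp_id"]]),
                effect_allele=row[cols["effect_allele"]],
                other_allele=row[cols["other_allele"]],
                beta_outcome=float(row[cols["beta_outcome"]]),
                se_outcome=float(row[cols["se_outcome"]]),
                cohort=str(row[cols["cohort"]]) if has_cohort else str(cohort),
                subtype=str(row[cols["subtype"]]) if has_subtype else Subtype(subtype),
                eaf=(None if _opt(row, cols.get("eaf")) is None else float(row[cols["eaf"]])),
            )
        except (FormatError, VocabularyError) as exc:
            kind = type(exc)
            raise kind(f"outcome table {path}, row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def group_outcomes(
    records: Iterable[OutcomeAssociation],
) -> dict[tuple[str, Subtype], list[OutcomeAssociation]]:
    """Group outcome records by (cohort, subtype)."""
    groups: dict[tuple[str, Subtype], list[OutcomeAssociation]] = {}
    for rec in records:
        groups.setdefault((rec.cohort, rec.subtype), []).append(rec)
    return groups


def write_exposure_table(
    records: Sequence[ExposureAssociation],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write exposure records as TSV in the given (default) dialect."""
    cols = _resolve_dialect(DEFAULT_EXPOSURE_DIALECT, dialect)
    rows = []
    for r in records:
        rows.append({
            cols["snp_id"]: r.snp_id,
            cols["chrom"]: r.chrom,
            cols["position"]: r.position,
            cols["effect_allele"]: r.effect_allele,
            cols["other_allele"]: r.other_allele,
            cols["beta_exposure"]: repr(r.beta_exposure),
            cols["se_exposure"]: repr(r.se_exposure),
            cols["f_stat"]: "" if r.f_stat is None else repr(r.f_stat),
            cols["locus"]: r.locus,
            cols["pathway"]: r.pathway.value,
            cols["eaf"]: "" if r.eaf is None else repr(r.eaf),
        })
    pd.DataFrame(rows, columns=[cols[k] for k in DEFAULT_EXPOSURE_DIALECT]).to_csv(
        path, sep="\t", index=False)


def write_outcome_table(
    records: Sequence[OutcomeAssociation],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write outcome records as TSV in the given (default) dialect."""
    cols = _resolve_dialect(DEFAULT_OUTCOME_DIALECT, dialect)
    rows = []
    for r in records:
        rows.append({
            cols["snp_id"]: r.snp_id,
            cols["effect_allele"]: r.effect_allele,
            cols["other_allele"]: r.other_allele,
            cols["beta_outcome"]: repr(r.beta_outcome),
            cols["se_outcome"]: repr(r.se_outcome),
            cols["cohort"]: r.cohort,
            cols["subtype"]: r.subtype.value,
            cols["eaf"]: "" if r.eaf is None else repr(r.eaf),
        })
    pd.DataFrame(rows, columns=[cols[k] for k in DEFAULT_OUTCOME_DIALECT]).to_csv(
        path, sep="\t", index=False)


def builtin_sunlight_instruments() -> list[ExposureAssociation]:
    """The four-SNP 25(OH)D instrument set (GC, CYP2R1, DHCR7, CYP24A1 loci).

    Per-allele effects on 25(OH)D with SEs and single-SNP F-statistics, the
    effect allele being the 25(OH)D-decreasing allele (all betas negative).
    Positions are GRCh37 and are metadata only.  rs12785878 and rs10741657
    act in vitamin D synthesis; rs2282679 and rs6013897 in transport and
    catabolism ("metabolism").  No allele frequencies are attached.
    """
    return [
        ExposureAssociation("rs2282679", "4", 72608383, "G", "T", -0.047, 0.013,
                            f_stat=13.38, locus="GC", pathway=Pathway.METABOLISM),
        ExposureAssociation("rs10741657", "11", 14914878, "G", "A", -0.052, 0.012,
                            f_stat=18.78, locus="CYP2R1", pathway=Pathway.SYNTHESIS),
        ExposureAssociation("rs12785878", "11", 71167449, "G", "T", -0.056, 0.013,
                            f_stat=18.29, locus="DHCR7", pathway=Pathway.SYNTHESIS),
        ExposureAssociation("rs6013897", "20", 52742479, "A", "T", -0.027, 0.015,
                            f_stat=3.13, locus="CYP24A1", pathway=Pathway.METABOLISM),
    ]


@dataclass
class AnalysisReport:
    """Structured output of one pipeline run.

    All sections are plain JSON-serialisable structures (dicts/lists of
    numbers and strings) so that a JSON round-trip is exact.  ``None``
    sections are permitted and are written as explicitly absent.
    """

    provenance: dict = field(default_factory=dict)
    estimates: list = field(default_factory=list)      # per (method, subtype) pooled rows
    egger: list = field(default_factory=list)          # per subtype slope + intercept
    forest: list = field(default_factory=list)         # per (method, subtype) cohort rows
    sensitivity: list | None = None
    power: list | None = None
    bonferroni: dict | None = None
    harmonization_log: list = field(default_factory=list)
    ld: list | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisReport":
        return cls(**{k: d.get(k) for k in (f.name for f in dataclasses.fields(cls))})


def _fmt(x, nd: int) -> str:
    return "" if x is None else f"{x:.{nd}f}"


def write_report(report: AnalysisReport, path: str | Path, format: str = "json") -> None:
    """Write an analysis report as JSON (full precision) or TSV (display precision).

    The JSON form round-trips exactly through :func:`read_report`.  The TSV
    form mirrors the published table layout: betas/SEs to 3 decimals, ORs and
    CI bounds to 2, P values to 3, with one section per report block and a
    forest-plot data table (per-cohort OR, CI, weight) per method/subtype.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n")
        return
    if format != "tsv":
        raise VocabularyError(f"unknown report format {format!r}")
    lines: list[str] = []
    lines.append("## estimates")
    lines.append("subtype\tmethod\tn_snps\tbeta\tse\tor\tci_low\tci_high\tp")
    for row in report.estimates:
        lines.append("\t".join([
            row["subtype"], row["method"], str(row["n_snps"]),
            _fmt(row["beta"], 3), _fmt(row["se"], 3), _fmt(row["or"], 2),
            _fmt(row["ci_low"], 2), _fmt(row["ci_high"], 2), _fmt(row["p"], 3),
        ]))
    lines.append("")
    lines.append("## egger")
    lines.append("subtype\tterm\testimate\tse\tci_low\tci_high\tp")
    for row in report.egger:
        for term in ("slope", "intercept"):
            t = row[term]
            lines.append("\t".join([
                row["subtype"], term, _fmt(t["estimate"], 3), _fmt(t["se"], 3),
                _fmt(t["ci_low"], 3), _fmt(t["ci_high"], 3), _fmt(t["p"], 3),
            ]))
    lines.append("")
    lines.append("## forest")
    lines.append("subtype\tmethod\tcohort\tor\tci_low\tci_high\tweight")
    for row in report.forest:
        lines.append("\t".join([
            row["subtype"], row["method"], row["cohort"], _fmt(row["or"], 2),
            _fmt(row["ci_low"], 2), _fmt(row["ci_high"], 2),
            "" if row["weight"] is None else f"{row['weight']:.4f}",
        ]))
    lines.append("")
    lines.append("## sensitivity")
    if report.sensitivity is None:
        lines.append("(absent)")
    else:
        lines.append("subtype\tanalysis\tlabel\tmethod\tn_snps\tbeta\tse\tor\tci_low\tci_high\tp\tdelta_beta")
        for row in report.sensitivity:
            for m, est in row["estimates"].items():
                if est is None:
                    lines.append("\t".join([row["subtype"], row["analysis"], row["label"], m,
                                            "", "", "", "", "", "", "", "not_estimable"]))
                else:
                    delta = row["comparison"].get(m)
                    lines.append("\t".join([
                        row["subtype"], row["analysis"], row["label"], m, str(est["n_snps"]),
                        _fmt(est["beta"], 3), _fmt(est["se"], 3), _fmt(est["or"], 2),
                        _fmt(est["ci_low"], 2), _fmt(est["ci_high"], 2), _fmt(est["p"], 3),
                        "" if delta is None else f"{delta:.4f}",
                    ]))
    lines.append("")
    lines.append("## power")
    if report.power is None:
        lines.append("(absent)")
    else:
        lines.append("label\tn_cases\tn_controls\tr2\talpha\tpower\tor_harmful\tor_protective")
        for row in report.power:
            lines.append("\t".join([
                row.get("label", ""), str(row["n_cases"]), str(row["n_controls"]),
                f"{row['r2']:g}", f"{row['alpha']:g}", f"{row['power']:g}",
                _fmt(row["or_harmful"], 2), _fmt(row["or_protective"], 2),
            ]))
    lines.append("")
    lines.append("## bonferroni")
    if report.bonferroni is None:
        lines.append("(absent)")
    else:
        lines.append("alpha\tm\tthreshold")
        b = report.bonferroni
        lines.append(f"{b['alpha']:g}\t{b['m']}\t{b['threshold']:.3f}")
    lines.append("")
    lines.append("## harmonization_log")
    lines.append("snp_id\tcohort\tsubtype\taction\treason")
    for row in report.harmonization_log:
        lines.append("\t".join([row["snp_id"], row["cohort"], row["subtype"],
                                row["action"], row.get("reason") or ""]))
    lines.append("")
    path.write_text("\n".join(lines))


def read_report(path: str | Path) -> AnalysisReport:
    """Read back a JSON report written by :func:`write_report`."""
    return AnalysisReport.from_dict(json.loads(Path(path).read_text()))
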