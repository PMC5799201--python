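"""Allele harmonisation, LD independence checks and instrument strength.

Summary statistics from two GWAS may report effects with respect to opposite
alleles, or on opposite strands.  Harmonisation aligns each outcome log-OR to
the exposure's effect allele so the per-SNP pair (X_k, Y_k) is interpretable.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from allele labels and
fall back to comparing effect-allele frequencies between datasets; when that
is ambiguous the SNP is excluded with an explicit reason — nothing is ever
dropped silently, because the instrument count changes every estimate.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InputError
from .summary_io import ExposureAssociation, OutcomeAssociation, Pathway, Subtype

__all__ = [
    "Action",
    "HarmonizedInstrument",
    "LdCheckResult",
    "harmonize_pair",
    "harmonize_dataset",
    "orient_increasing",
    "check_ld_independence",
    "f_statistic",
    "se_from_f",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Action(str, enum.Enum):
    KEPT_AS_IS = "kept_as_is"
    SIGN_FLIPPED = "sign_flipped"
    STRAND_FLIPPED = "strand_flipped"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One allele-aligned (X_k, sigma_X, Y_k, sigma_Y) pair ready for estimation."""

    snp_id: str
    x: float
    sigma_x: float
    y: float
    sigma_y: float
    action: Action
    exclusion_reason: str | None = None
    pathway: Pathway = Pathway.UNKNOWN
    cohort: str = ""
    subtype: Subtype = Subtype.ALL_GLIOMA

    @property
    def included(self) -> bool:
        return self.action is not Action.EXCLUDED


@dataclass(frozen=True)
class LdCheckResult:
    """Pairwise linkage-disequilibrium verdict at a given r-squared threshold.

    ``independent`` is None (status "unchecked") when no r-squared value was
    available for the pair.
    """

    snp_a: str
    snp_b: str
    r2: float | None
    independent: bool | None

    @property
    def status(self) -> str:
        if self.independent is None:
            return "unchecked"
        return "independent" if self.independent else "linked"


def _is_palindromic(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def harmonize_pair(
    exp: ExposureAssociation,
    out: OutcomeAssociation,
    palindromic_freq_window: float = 0.08,
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure record's effect allele.

    Resolution order: direct allele match (kept as is); swapped
    effect/other alleles (outcome beta negated); match after complementing
    the outcome alleles (strand flip), with the swap logic re-applied.
    Palindromic SNPs are resolved by effect-allele-frequency concordance when
    both sides report a frequency outside ``0.5 +/- palindromic_freq_window``,
    and excluded as ``palindromic_ambiguous`` otherwise.  Irreconcilable
    allele sets yield an ``allele_mismatch`` exclusion.
    """
    if exp.snp_id != out.snp_id:
        raise InputError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    base = dict(snp_id=exp.snp_id, x=exp.beta_exposure, sigma_x=exp.se_exposure,
                sigma_y=out.se_outcome, pathway=exp.pathway,
                cohort=out.cohort, subtype=out.subtype)
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if _is_palindromic(e_ea, e_oa):
        # Strand is unknowable from labels; align labels first, then use
        # frequency concordance to decide whether the two studies measured
        # the same allele or its complement.
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return HarmonizedInstrument(y=out.beta_outcome, action=Action.EXCLUDED,
                                        exclusion_reason="allele_mismatch", **base)
        y, o_eaf = out.beta_outcome, out.eaf
        if o_ea != e_ea:  # labels swapped: refer outcome effect to exposure EA
            y = -y
            o_eaf = None if o_eaf is None else 1.0 - o_eaf
        w = palindromic_freq_window
        e_eaf = exp.eaf
        if e_eaf is None or o_eaf is None or abs(e_eaf - 0.5) <= w or abs(o_eaf - 0.5) <= w:
            return HarmonizedInstrument(y=out.beta_outcome, action=Action.EXCLUDED,
                                        exclusion_reason="palindromic_ambiguous", **base)
        if (e_eaf < 0.5) == (o_eaf < 0.5):
            return HarmonizedInstrument(y=y, action=Action.KEPT_AS_IS, **base)
        # Frequencies discordant: outcome is on the other strand, where the
        # labelled EA denotes the exposure's other allele.
        return HarmonizedInstrument(y=-y, action=Action.SIGN_FLIPPED, **base)

    if (o_ea, o_oa) == (e_ea, e_oa):
        return HarmonizedInstrument(y=out.beta_outcome, action=Action.KEPT_AS_IS, **base)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return HarmonizedInstrument(y=-out.beta_outcome, action=Action.SIGN_FLIPPED, **base)
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return HarmonizedInstrument(y=out.beta_outcome, action=Action.STRAND_FLIPPED, **base)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return HarmonizedInstrument(y=-out.beta_outcome, action=Action.STRAND_FLIPPED, **base)
    return HarmonizedInstrument(y=out.beta_outcome, action=Action.EXCLUDED,
                                exclusion_reason="allele_mismatch", **base)


def harmonize_dataset(
    exposures: Sequence[ExposureAssociation],
    outcomes: Sequence[OutcomeAssociation],
    palindromic_freq_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Harmonise every outcome record against its exposure record.

    Outcome records whose SNP has no exposure record are ignored (they are
    not instruments); exposure SNPs missing from the outcome side simply
    yield no pair for that cohort.
    """
    by_snp = {e.snp_id: e for e in exposures}
    pairs: list[HarmonizedInstrument] = []
    for out in outcomes:
        exp = by_snp.get(out.snp_id)
        if exp is not None:
            pairs.append(harmonize_pair(exp, out, palindromic_freq_window))
    return pairs


def orient_increasing(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Re-express each pair on the scale of *increasing* exposure.

    Jointly negates (x, y) wherever x < 0 so that an OR below 1 reads as
    "higher 25(OH)D is protective".  All estimators are invariant to this
    per-instrument joint negation; it is presentation only.
    """
    oriented = []
    for ins in instruments:
        if ins.included and ins.x < 0:
            oriented.append(replace(ins, x=-ins.x, y=-ins.y))
        else:
            oriented.append(ins)
    return oriented


def harmonization_log(instruments: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular log of every harmonisation decision (snp, cohort, action, reason)."""
    return pd.DataFrame([
        {"snp_id": i.snp_id, "cohort": i.cohort, "subtype": i.subtype.value,
         "action": i.action.value, "reason": i.exclusion_reason or ""}
        for i in instruments
    ])


def check_ld_independence(
    snp_ids: Sequence[str],
    r2_matrix: pd.DataFrame | np.ndarray | None = None,
    threshold: float = 0.001,
) -> list[LdCheckResult]:
    """Check pairwise LD independence against a precomputed r-squared matrix.

    The matrix may be a labelled square DataFrame (rows/columns indexed by
    rsID) or a square ndarray in ``snp_ids`` order.  With no matrix, every
    pair is returned "unchecked" and a warning is emitted — the analysis can
    proceed but the independence assumption is then unverified.
    """
    ids = list(snp_ids)
    if r2_matrix is None:
        warnings.warn("no LD matrix supplied; instrument independence is unchecked",
                      stacklevel=2)
        return [LdCheckResult(a, b, None, None) for a, b in itertools.combinations(ids, 2)]
    if isinstance(r2_matrix, pd.DataFrame):
        missing = [s for s in ids if s not in r2_matrix.index or s not in r2_matrix.columns]
        if missing:
            raise InputError(f"LD matrix does not cover SNPs: {missing}")
        mat = r2_matrix.loc[ids, ids].to_numpy(dtype=float)
    else:
        mat = np.asarray(r2_matrix, dtype=float)
        if mat.shape != (len(ids), len(ids)):
            raise InputError(f"LD matrix shape {mat.shape} does not match {len(ids)} SNPs")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise InputError("LD matrix is not symmetric")
    if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
        raise InputError("LD r2 values must lie in [0, 1]")
    results = []
    for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
        r2 = float(mat[i, j])
        results.append(LdCheckResult(a, b, r2, r2 < threshold))
    return results


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F-statistic, (beta/se)^2."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def se_from_f(beta: float, f: float) -> float:
    """Recover a standard error from an effect and its F-statistic, |beta|/sqrt(F)."""
    if not f > 0:
        raise DomainError(f"F must be > 0, got {f}")
    return abs(beta) / math.sqrt(f)
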