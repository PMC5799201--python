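"""Fixed-effect meta-analysis of per-cohort MR estimates and forest-plot data.

The pipeline estimates the causal effect within each outcome cohort and then
pools the cohort-level estimates by inverse-variance weighting under a
fixed-effect model:

    beta_pooled = sum_i w_i beta_i / sum_i w_i,   w_i = 1 / se_i^2
    se_pooled   = sqrt( 1 / sum_i w_i )

Cochran's Q and I^2 are computed as diagnostics and logged but never gate
results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate
from .exceptions import EstimationError

__all__ = ["MetaResult", "fixed_effect_meta", "pool_fixed", "forest_data", "plot_forest"]


def pool_fixed(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, np.ndarray]:
    """Inverse-variance fixed-effect pooling; returns (beta, se, normalised weights)."""
    if len(betas) == 0:
        raise EstimationError("cannot pool an empty list of estimates")
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise EstimationError("all component SEs must be > 0")
    w = s ** -2.0
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return beta, se, w / np.sum(w)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with its per-cohort components and normalised weights."""

    pooled: MREstimate
    components: tuple[tuple[str, MREstimate, float], ...]  # (cohort, estimate, weight)
    method: str
    subtype: str
    q: float
    i2: float

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "components": [
                {"cohort": c, "estimate": e.to_dict(), "weight": w}
                for c, e, w in self.components
            ],
            "method": self.method,
            "subtype": self.subtype,
            "q": self.q,
            "i2": self.i2,
        }


def fixed_effect_meta(
    estimates: Sequence[tuple[str, MREstimate]],
    alpha: float = 0.05,
    subtype: str = "",
) -> MetaResult:
    """Pool per-cohort MR estimates under a fixed-effect model."""
    if not estimates:
        raise EstimationError("cannot meta-analyse an empty list of estimates")
    methods = {e.method for _, e in estimates}
    if len(methods) > 1:
        raise EstimationError(f"cannot pool estimates from mixed methods: {sorted(methods)}")
    labels = [c for c, _ in estimates]
    betas = [e.beta for _, e in estimates]
    ses = [e.se for _, e in estimates]
    beta, se, weights = pool_fixed(betas, ses)
    w_raw = np.asarray(ses, dtype=float) ** -2.0
    q = float(np.sum(w_raw * (np.asarray(betas) - beta) ** 2))
    df = len(betas) - 1
    i2 = float(max(0.0, (q - df) / q)) if q > 0 and df > 0 else 0.0
    method = methods.pop()
    n_snps = max(e.n_snps for _, e in estimates)
    pooled = MREstimate.from_beta_se(method, beta, se, n_snps, alpha)
    components = tuple(
        (label, est, float(w)) for (label, est), w in zip(estimates, weights)
    )
    return MetaResult(pooled=pooled, components=components, method=method,
                      subtype=subtype, q=q, i2=i2)


def forest_data(meta: MetaResult) -> pd.DataFrame:
    """Forest-plot table: one row per cohort plus a summary row.

    Columns: cohort, or, ci_low, ci_high, weight.  Weights are normalised to
    sum to 1 over the cohorts; the summary row carries no weight (NaN).
    """
    rows = [
        {"cohort": c, "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
         "weight": w}
        for c, e, w in meta.components
    ]
    p = meta.pooled
    rows.append({"cohort": "Pooled", "or": p.or_, "ci_low": p.ci_low,
                 "ci_high": p.ci_high, "weight": float("nan")})
    return pd.DataFrame(rows, columns=["cohort", "or", "ci_low", "ci_high", "weight"])


def plot_forest(meta: MetaResult, path: str, title: str = "") -> None:
    """Render a minimal forest plot (squares sized by weight, summary diamond)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = forest_data(meta)
    n = len(df)
    fig, ax = plt.subplots(figsize=(6, 0.5 * n + 1.5))
    for i, row in df.iterrows():
        ypos = n - 1 - i
        ax.plot([row["ci_low"], row["ci_high"]], [ypos, ypos], color="black", lw=1)
        if row["cohort"] == "Pooled":
            ax.plot(row["or"], ypos, marker="D", color="firebrick", markersize=9)
        else:
            size = 4 + 14 * row["weight"]
            ax.plot(row["or"], ypos, marker="s", color="steelblue", markersize=size)
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(range(n))
    ax.set_yticklabels(df["cohort"][::-1])
    ax.set_xlabel("Odds ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
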