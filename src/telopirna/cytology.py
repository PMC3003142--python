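"""Anaphase/telophase chromosome-bridge statistics.

Each embryo is one independent observation: its bridge frequency is the
ratio of bridged anaphase/telophase (A/T) figures to the total A/T
figures scored in that embryo.  Genotype summaries report the mean of
per-embryo ratios with its standard error (never a pooled-figures
ratio), a one-way ANOVA across genotypes, and two-tailed pairwise
t-tests — Welch's unequal-variance test by default, with a pooled
Student's option.  Ratios are analyzed untransformed and pairwise
p-values are reported raw; a Bonferroni flag is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeSummary",
    "BridgeAnalysis",
    "per_embryo_ratios",
    "summarize_bridges",
]

COUNT_COLUMNS = ["genotype", "embryo_id", "bridged", "total"]


@dataclass
class GenotypeSummary:
    genotype: str
    n_embryos: int
    mean_ratio: float
    sem: float  # NaN when < 2 embryos (flagged, not fatal)

    @property
    def sem_defined(self) -> bool:
        return not math.isnan(self.sem)


@dataclass
class BridgeAnalysis:
    summaries: dict[str, GenotypeSummary]
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genotype": s.genotype,
                    "n_embryos": s.n_embryos,
                    "mean_ratio": s.mean_ratio,
                    "sem": s.sem,
                }
                for s in self.summaries.values()
            ]
        )


def per_embryo_ratios(counts: pd.DataFrame) -> pd.Series:
    """bridged/total per embryo, validated."""
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (counts["total"] < 1).any():
        raise ValueError("every embryo must have total >= 1 scored figures")
    if ((counts["bridged"] < 0) | (counts["bridged"] > counts["total"])).any():
        raise ValueError("bridged counts must lie in [0, total]")
    return counts["bridged"] / counts["total"]


def summarize_bridges(
    counts: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    welch: bool = True,
    bonferroni: bool = False,
) -> BridgeAnalysis:
    """Genotype means/SEMs, one-way ANOVA, and requested pairwise t-tests.

    *pairs* defaults to all genotype pairs in table order.  With
    ``bonferroni=True`` pairwise p-values are multiplied by the number
    of tests (capped at 1).
    """
    counts = counts.copy()
    counts["ratio"] = per_embryo_ratios(counts)
    groups: dict[str, np.ndarray] = {
        g: grp["ratio"].to_numpy(dtype=float)
        for g, grp in counts.groupby("genotype", sort=False)
    }
    summaries = {
        g: GenotypeSummary(
            genotype=g,
            n_embryos=len(r),
            mean_ratio=float(r.mean()),
            sem=float(stats.sem(r)) if len(r) > 1 else math.nan,
        )
        for g, r in groups.items()
    }

    if len(groups) > 1 and all(len(r) > 1 for r in groups.values()):
        anova_f, anova_p = stats.f_oneway(*groups.values())
    else:
        anova_f = anova_p = math.nan

    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown genotype in pair ({a!r}, {b!r})")
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
        if bonferroni:
            p = min(1.0, p * len(pairs))
        rows.append(
            {
                "genotype_a": a,
                "genotype_b": b,
                "t": float(t),
                "p": float(p),
                "significant_0.05": bool(p < 0.05),
            }
        )
    pairwise = pd.DataFrame(rows)
    return BridgeAnalysis(summaries, float(anova_f), float(anova_p), pairwise)
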