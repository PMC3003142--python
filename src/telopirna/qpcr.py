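"""Efficiency-corrected qPCR quantification.

Two quantifications are implemented on top of per-primer standard
curves fitted from ten-fold dilution series:

* ChIP percent input — the fraction of input chromatin recovered in an
  immunoprecipitate, corrected for the fraction of chromatin set aside
  as input and for the primer pair's amplification efficiency E
  (estimated as ``10**(-1/slope)`` from the Ct-vs-log10(dilution) fit),
  plus mutant/wild-type fold-change tables.

* Relative genomic copy number of a repeated element against a
  single-copy internal reference gene; with both efficiencies equal to
  2 this reduces exactly to the textbook ``2**(-ddCt)`` form.

Replicate Cts are averaged on the cycle scale before exponentiation
(geometric averaging of quantities); Ct >= 40 is treated as a
non-detect and excluded with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ChIPResult",
    "CopyNumberResult",
    "fit_efficiency",
    "percent_input",
    "fold_vs_wt",
    "copy_number",
    "NONDETECT_CT",
]

NONDETECT_CT = 40.0
#: plausible bounds on a fitted per-cycle amplification factor
EFFICIENCY_BOUNDS = (1.0, 2.2)


@dataclass
class StandardCurve:
    """Fitted Ct-vs-log10(dilution) line for one primer pair."""

    primer_pair: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    @property
    def efficiency_ok(self) -> bool:
        lo, hi = EFFICIENCY_BOUNDS
        return lo < self.efficiency <= hi


@dataclass
class ChIPResult:
    sample: str
    primer_pair: str
    percent_input: float
    sd: float


@dataclass
class CopyNumberResult:
    sample: str
    element: str
    fold_vs_control: float
    sd: float


def _clean_cts(cts: Sequence[float], label: str = "") -> np.ndarray:
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise ValueError(f"no Ct values{' for ' + label if label else ''}")
    if np.any((arr <= 0) | (arr >= 45)):
        raise ValueError(f"Ct outside (0, 45){' for ' + label if label else ''}")
    keep = arr < NONDETECT_CT
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} non-detect Ct(s) >= {NONDETECT_CT}"
            f"{' for ' + label if label else ''}",
            stacklevel=3,
        )
        arr = arr[keep]
    if arr.size == 0:
        raise ValueError(f"all Cts non-detect{' for ' + label if label else ''}")
    return arr


def fit_efficiency(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    primer_pair: str = "",
) -> StandardCurve:
    """Least-squares fit of Ct on log10(dilution); E = 10**(-1/slope).

    *points* is an iterable of (log10_dilution, ct) or a DataFrame with
    ``log10_dilution`` and ``ct`` columns (replicates welcome).
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_dilution"].to_numpy(dtype=float)
        y = points["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilution points")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(
            "standard-curve slope is non-negative; Ct must fall as template "
            "concentration rises — check the dilution orientation"
        )
    curve = StandardCurve(
        primer_pair=primer_pair,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(len(x)),
    )
    if not curve.efficiency_ok:
        warnings.warn(
            f"fitted efficiency {curve.efficiency:.3f} outside "
            f"{EFFICIENCY_BOUNDS} for {primer_pair or 'primer pair'}",
            stacklevel=2,
        )
    return curve


def _log_e(x: float, efficiency: float) -> float:
    return math.log(x) / math.log(efficiency)


def percent_input(
    ip_cts: Sequence[float],
    input_cts: Sequence[float],
    efficiency: float,
    input_fraction: float = 1.0,
    sample: str = "",
    primer_pair: str = "",
) -> ChIPResult:
    """Percent of input chromatin recovered by the IP, efficiency-corrected.

    The input aliquot is a fraction ``f`` of the chromatin the IP saw, so
    its Ct is first shifted to the whole-input equivalent
    ``adjusted = mean_input_Ct - log_E(1/f)`` (more template, fewer
    cycles), then ``%input = 100 * E**(adjusted - IP_Ct)``, which equals
    ``100 * f * E**(input_Ct - IP_Ct)``.  The SD combines the replicate
    standard errors of both Ct means by the delta method.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    ip = _clean_cts(ip_cts, f"IP {sample}/{primer_pair}")
    inp = _clean_cts(input_cts, f"input {sample}/{primer_pair}")
    adjusted_input = float(inp.mean()) - _log_e(1.0 / input_fraction, efficiency)
    pct = 100.0 * efficiency ** (adjusted_input - float(ip.mean()))
    sem2 = 0.0
    for arr in (ip, inp):
        if arr.size > 1:
            sem2 += float(arr.var(ddof=1)) / arr.size
    sd = pct * math.log(efficiency) * math.sqrt(sem2)
    return ChIPResult(sample, primer_pair, pct, sd)


def fold_vs_wt(
    results: Sequence[ChIPResult], wt_sample: str = "wt"
) -> pd.DataFrame:
    """Mutant %input divided by wild-type %input, per primer pair."""
    df = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "primer_pair": r.primer_pair,
                "percent_input": r.percent_input,
                "sd": r.sd,
            }
            for r in results
        ]
    )
    wt = df[df["sample"] == wt_sample].set_index("primer_pair")
    if wt.empty:
        raise ValueError(f"no wild-type sample {wt_sample!r} in results")
    rows = []
    for r in results:
        if r.primer_pair not in wt.index:
            raise ValueError(f"no wild-type value for primer pair {r.primer_pair!r}")
        wt_pct = float(wt.loc[r.primer_pair, "percent_input"])
        defined = wt_pct > 0
        rows.append(
            {
                "sample": r.sample,
                "primer_pair": r.primer_pair,
                "percent_input": r.percent_input,
                "fold_vs_wt": r.percent_input / wt_pct if defined else math.nan,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def copy_number(
    target_cts: dict[str, Sequence[float]],
    reference_cts: dict[str, Sequence[float]],
    target_efficiency: float,
    reference_efficiency: float,
    control_sample: str,
    element: str = "",
) -> list[CopyNumberResult]:
    """Element copy number per sample relative to a control sample.

    The relative quantity in a sample is ``E_t**(-Ct_t) / E_r**(-Ct_r)``
    (target normalized to the single-copy reference); the reported fold
    is that quantity divided by the control sample's.  With both
    efficiencies 2 this is exactly ``2**(-ddCt)``.
    """
    if control_sample not in target_cts or control_sample not in reference_cts:
        raise ValueError(f"control sample {control_sample!r} missing measurements")
    if target_efficiency <= 1 or reference_efficiency <= 1:
        raise ValueError("efficiencies must exceed 1")

    def rel_quantity(sample: str) -> tuple[float, float]:
        t = _clean_cts(target_cts[sample], f"target {sample}")
        r = _clean_cts(reference_cts[sample], f"reference {sample}")
        q = target_efficiency ** (-float(t.mean())) / reference_efficiency ** (
            -float(r.mean())
        )
        var = 0.0
        if t.size > 1:
            var += math.log(target_efficiency) ** 2 * float(t.var(ddof=1)) / t.size
        if r.size > 1:
            var += (
                math.log(reference_efficiency) ** 2 * float(r.var(ddof=1)) / r.size
            )
        return q, math.sqrt(var)  # sd on the log-quantity scale

    q_control, _ = rel_quantity(control_sample)
    out = []
    for sample in target_cts:
        if sample not in reference_cts:
            raise ValueError(f"no reference Cts for sample {sample!r}")
        q, log_sd = rel_quantity(sample)
        fold = q / q_control
        out.append(CopyNumberResult(sample, element, fold, fold * log_sd))
    return out
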