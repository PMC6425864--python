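"""Efficiency-corrected relative qPCR quantification.

Amplification efficiency (the per-cycle amplification factor, 2 for perfect
doubling) is estimated from a dilution standard curve: ordinary least
squares of Cp on log10 relative template amount gives a slope (Cp per log10
dilution, negative for any valid curve) and

    efficiency = 10^(-1/slope).

Fold induction of a target gene relative to a reference gene between a
control and an experimental group is

    fold = eff_target^dCp_target / eff_reference^dCp_reference,

with dCp oriented as (control - experimental) mean Cp, so that induction
(earlier crossing in the experimental group) yields positive dCp and
fold > 1.  This orientation is the most common sign bug in relative
quantification; it is fixed here and asserted in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "FoldResult",
    "efficiency_from_slope",
    "fit_standard_curve",
    "fold_induction",
    "plate_to_folds",
]

#: Efficiencies above this are flagged as implausible rather than rejected.
DEFAULT_EFFICIENCY_CEILING = 2.2


def efficiency_from_slope(slope: float) -> float:
    """Amplification factor per cycle from the standard-curve slope.

    ``efficiency = 10^(-1/slope)``; a perfect-doubling assay has slope
    -1/log10(2) = -3.3219 and efficiency 2.
    """
    if not (math.isfinite(slope) and slope < 0):
        raise ValueError(f"standard-curve slope must be finite and < 0, got {slope}")
    return 10.0 ** (-1.0 / slope)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution standard curve and derived efficiency."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_levels: int
    plausible: bool = True
    low_r2: bool = False

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "efficiency": self.efficiency,
            "n_levels": self.n_levels,
            "plausible": self.plausible,
            "low_r2": self.low_r2,
        }


def fit_standard_curve(
    dilution_log10: Sequence[float],
    cp: Sequence[float],
    *,
    r2_floor: float = 0.98,
    efficiency_ceiling: float = DEFAULT_EFFICIENCY_CEILING,
) -> StandardCurve:
    """OLS line of Cp on log10 relative template amount.

    Requires >= 3 dilution levels and a negative fitted slope.  Efficiencies
    above ``efficiency_ceiling`` or R^2 below ``r2_floor`` set warning flags
    rather than failing.
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cp, dtype=float)
    if x.size != y.size:
        raise ValueError("dilution and Cp arrays must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 dilution levels for a standard curve")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"fitted standard-curve slope is non-negative ({res.slope:.4g}); invalid curve")
    eff = efficiency_from_slope(res.slope)
    r2 = float(res.rvalue**2)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        efficiency=float(eff),
        n_levels=int(np.unique(x).size),
        plausible=bool(1.0 < eff <= efficiency_ceiling),
        low_r2=bool(r2 < r2_floor),
    )


def fold_induction(
    eff_target: float, dcp_target: float, eff_reference: float, dcp_reference: float
) -> float:
    """fold = eff_target^dCp_target / eff_reference^dCp_reference.

    dCp values are (control - experimental) mean Cp differences.
    """
    for name, e in (("target", eff_target), ("reference", eff_reference)):
        if not (math.isfinite(e) and e > 1.0):
            raise ValueError(f"{name} efficiency must be > 1, got {e}")
    return eff_target**dcp_target / eff_reference**dcp_reference


@dataclass(frozen=True)
class FoldResult:
    """Fold induction for one experimental condition with a delta-method CI."""

    condition: str
    fold: float
    log_fold_se: float
    ci_low: float
    ci_high: float
    dcp_target: float
    dcp_reference: float

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "fold": self.fold,
            "log_fold_se": self.log_fold_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "dcp_target": self.dcp_target,
            "dcp_reference": self.dcp_reference,
        }


def _group_cp(plate: pd.DataFrame, gene: str, condition: str) -> np.ndarray:
    sel = plate[(plate["gene"] == gene) & (plate["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"plate has no rows for gene {gene!r} in condition {condition!r}")
    cp = sel["Cp"].to_numpy(dtype=float)
    if np.any(cp <= 0) or np.any(cp >= 45) or not np.all(np.isfinite(cp)):
        raise ValueError(f"Cp values for {gene!r}/{condition!r} must lie in (0, 45)")
    return cp


def plate_to_folds(
    plate: pd.DataFrame,
    target: str,
    reference: str,
    eff_target: float,
    eff_reference: float,
    *,
    control: str = "control",
    level: float = 0.95,
) -> list:
    """Fold induction per experimental condition vs the control group.

    Replicates are aggregated as mean Cp per (gene, condition) before
    differencing.  Replicate Cp variability propagates to the fold by the
    delta method on the Cp means:

        var(log fold) = ln(eff_t)^2 var(dCp_t) + ln(eff_r)^2 var(dCp_r)

    with var(dCp) the summed standard errors of the two group means.
    """
    for col in ("gene", "condition", "replicate", "Cp"):
        if col not in plate.columns:
            raise ValueError(f"plate must have a {col!r} column")
    conditions = [c for c in plate["condition"].unique() if c != control]
    if control not in set(plate["condition"]):
        raise ValueError(f"plate has no control condition {control!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)

    out = []
    for cond in conditions:
        folds = {}
        var_log = 0.0
        dcps = {}
        for gene, eff in ((target, eff_target), (reference, eff_reference)):
            ctl = _group_cp(plate, gene, control)
            exp = _group_cp(plate, gene, cond)
            dcp = ctl.mean() - exp.mean()
            var_dcp = (ctl.var(ddof=1) / ctl.size if ctl.size > 1 else 0.0) + (
                exp.var(ddof=1) / exp.size if exp.size > 1 else 0.0
            )
            dcps[gene] = dcp
            var_log += (math.log(eff) ** 2) * var_dcp
        fold = fold_induction(eff_target, dcps[target], eff_reference, dcps[reference])
        se = math.sqrt(var_log)
        out.append(
            FoldResult(
                condition=cond,
                fold=float(fold),
                log_fold_se=float(se),
                ci_low=float(fold * math.exp(-z * se)),
                ci_high=float(fold * math.exp(z * se)),
                dcp_target=float(dcps[target]),
                dcp_reference=float(dcps[reference]),
            )
        )
    return out
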