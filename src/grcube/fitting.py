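"""Four-parameter logistic and mechanistic fitting of dose-response data.

The 4PL follows the convention of standard nonlinear-regression software:

    response = bottom + (top - bottom) / (1 + 10^(hill * (log10 EC50 - log10 dose)))

parameterized on pEC50 = -log10(EC50), so hill > 0 gives an increasing
agonist curve.  Mass-action curves from the equilibrium cube have hill = 1;
``hill`` is free by default but can be fixed to 1.

Datasets are tidy pandas DataFrames with columns ``dose_M``, ``response``
and optionally ``replicate`` and ``condition``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dose_response import response_at
from .equilibrium import EquilibriumParams, Milieu, ResponseSpec

__all__ = [
    "LogisticFit",
    "FitError",
    "UnderIdentifiedError",
    "MechanisticFit",
    "logistic4",
    "fit_logistic4",
    "fit_mechanism",
    "compare_fit_parameters",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        self.last_iterate = last_iterate
        super().__init__(message)


class UnderIdentifiedError(ValueError):
    """The declared free-parameter set is not identifiable from the data."""


def logistic4(dose: np.ndarray, bottom: float, top: float, pec50: float, hill: float) -> np.ndarray:
    """4PL response at the given doses (molar)."""
    logdose = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (-pec50 - logdose)))


@dataclass(frozen=True)
class LogisticFit:
    """Fitted 4PL parameters with asymptotic (Wald) standard errors."""

    bottom: float
    top: float
    pEC50: float
    hill: float
    se: Mapping[str, float]
    residual_sd: float
    n_obs: int
    converged: bool
    hill_fixed: bool = False
    plateau_spanned: bool = True
    degenerate: bool = False

    @property
    def EC50(self) -> float:
        return 10.0 ** (-self.pEC50)

    @property
    def Rmax(self) -> float:
        return self.top

    def parameter(self, name: str) -> tuple:
        """(estimate, SE) for one of bottom/top/pEC50/hill."""
        return getattr(self, name if name != "Rmax" else "top"), self.se[name if name != "Rmax" else "top"]

    def confint(self, name: str, level: float = 0.95) -> tuple:
        est, se = self.parameter(name)
        z = stats.norm.ppf(0.5 + level / 2.0)
        return est - z * se, est + z * se

    def to_dict(self) -> dict:
        return {
            "bottom": self.bottom,
            "top": self.top,
            "pEC50": self.pEC50,
            "hill": self.hill,
            "se": dict(self.se),
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "hill_fixed": self.hill_fixed,
            "plateau_spanned": self.plateau_spanned,
            "degenerate": self.degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _check_dataset(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("dose_M", "response"):
        if col not in data.columns:
            raise ValueError(f"dataset must have a {col!r} column")
    d = data[data["dose_M"] > 0].copy()
    if not np.all(np.isfinite(d["response"])):
        raise ValueError("responses must be finite")
    if d["dose_M"].nunique() < 4:
        raise ValueError("need >= 4 distinct positive doses for 4PL fitting")
    return d


def fit_logistic4(
    data: pd.DataFrame,
    *,
    hill: str = "free",
    weights: "np.ndarray | None" = None,
) -> LogisticFit:
    """Least-squares 4PL fit.

    ``hill="free"`` fits the slope; ``hill="fixed1"`` pins it to the
    mass-action value 1.  Starting values: bottom/top from the extreme mean
    responses, pEC50 from the dose at half range by interpolation, hill 1.
    Unweighted by default; optional per-observation weights (1/variance).
    """
    if hill not in ("free", "fixed1"):
        raise ValueError("hill must be 'free' or 'fixed1'")
    d = _check_dataset(data)
    x = d["dose_M"].to_numpy(dtype=float)
    y = d["response"].to_numpy(dtype=float)
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, dtype=float))

    means = d.groupby("dose_M")["response"].mean().sort_index()
    b0, t0 = float(means.min()), float(means.max())
    halfway = 0.5 * (b0 + t0)
    logd = np.log10(means.index.to_numpy())
    mv = means.to_numpy()
    # dose at half range by linear interpolation on the mean curve
    crossing = np.flatnonzero(np.diff(np.sign(mv - halfway)) != 0)
    if crossing.size and mv[-1] != mv[0]:
        i = crossing[0]
        frac = (halfway - mv[i]) / (mv[i + 1] - mv[i]) if mv[i + 1] != mv[i] else 0.5
        p0 = -(logd[i] + frac * (logd[i + 1] - logd[i]))
    else:
        p0 = -float(np.median(logd))
    span = max(t0 - b0, 1e-6 * max(abs(t0), 1.0))

    fixed = hill == "fixed1"

    def model(theta):
        bt, tp, pe = theta[:3]
        hl = 1.0 if fixed else theta[3]
        return logistic4(x, bt, tp, pe, hl)

    def resid(theta):
        return w * (model(theta) - y)

    theta0 = np.array([b0, t0, p0] if fixed else [b0, t0, p0, 1.0])
    sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError("4PL fit did not converge", last_iterate=sol.x)

    theta = sol.x
    n, k = y.size, theta.size
    dof = max(n - k, 1)
    rss = float(np.sum(sol.fun**2))
    s2 = rss / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)

    names = ["bottom", "top", "pEC50"] + ([] if fixed else ["hill"])
    se = dict(zip(names, ses))
    if fixed:
        se["hill"] = 0.0
    bt, tp, pe = theta[:3]
    hl = 1.0 if fixed else theta[3]
    if tp < bt:  # reorient a mirrored solution (top/bottom swap with hill sign)
        bt, tp, hl = tp, bt, -hl
        se["bottom"], se["top"] = se["top"], se["bottom"]
    degenerate = (tp - bt) <= 1e-8 * max(abs(tp), 1.0)
    spanned = x.max() >= 10.0 ** (-pe)
    return LogisticFit(
        bottom=float(bt),
        top=float(tp),
        pEC50=float(pe),
        hill=float(hl),
        se={k_: float(v) for k_, v in se.items()},
        residual_sd=float(math.sqrt(s2)),
        n_obs=int(n),
        converged=True,
        hill_fixed=fixed,
        plateau_spanned=bool(spanned),
        degenerate=bool(degenerate),
    )


def compare_fit_parameters(fit_a: LogisticFit, fit_b: LogisticFit, parameter: str) -> dict:
    """Normal-theory z-test on a fitted parameter between two fits.

    z = (a - b)/sqrt(SEa^2 + SEb^2), two-sided p from the standard normal,
    reported per comparison without multiplicity correction.
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("both fits must have converged")
    a, sa = fit_a.parameter(parameter)
    b, sb = fit_b.parameter(parameter)
    se = math.hypot(sa, sb)
    if se == 0:
        raise ValueError("combined standard error is zero")
    z = (a - b) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {"difference": a - b, "se": se, "z": z, "p_value": p, "parameter": parameter}


# ---------------------------------------------------------------------------
# mechanistic fitting


_GLOBAL_FREE = ("Ka", "Kc", "Kd", "alpha", "beta", "gamma", "delta", "epsilon")


@dataclass(frozen=True)
class MechanisticFit:
    """Joint mechanistic fit across linked conditions."""

    estimates: Mapping[str, float]
    se: Mapping[str, float]
    scales: Mapping[str, float]
    scale_se: Mapping[str, float]
    residual_sd: float
    n_obs: int
    converged: bool
    identifiability: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "se": dict(self.se),
            "scales": dict(self.scales),
            "scale_se": dict(self.scale_se),
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "identifiability": self.identifiability,
        }


def fit_mechanism(
    datasets: Mapping[str, pd.DataFrame],
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    *,
    free: Sequence[str] = (),
    free_scales: bool = False,
    scale_target: str = "Rtot",
    fixed: "Mapping[str, float] | None" = None,
) -> MechanisticFit:
    """Joint least squares of the equilibrium model across conditions.

    ``datasets`` maps condition label -> tidy dataset; all conditions share
    the mechanistic parameters except a per-condition abundance scale on
    ``scale_target`` ("Rtot" or "C") when ``free_scales`` is set (the first
    condition's scale is anchored at 1, making epsilon identifiable).

    A structural screen refuses under-identified declarations: a single
    curve pins at most two independent quantities (effective EC50 and Rmax),
    so the free set may not exceed 2 x number of conditions, and
    ``epsilon``/``Rtot``-like pure scale factors must not be jointly free.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    fixed = dict(fixed or {})
    free = list(free)
    for f in free:
        if f not in _GLOBAL_FREE:
            raise ValueError(f"unknown free parameter {f!r}; choose from {_GLOBAL_FREE}")

    conditions = list(datasets)
    n_cond = len(conditions)
    n_scales = n_cond - 1 if free_scales else 0
    n_free = len(free) + n_scales
    if n_free > 2 * n_cond:
        raise UnderIdentifiedError(
            f"{n_free} free quantities declared but {n_cond} condition(s) identify at most "
            f"{2 * n_cond} (each curve pins only an effective EC50 and an Rmax); "
            "link more conditions or fix parameters"
        )
    if "epsilon" in free and free_scales and scale_target == "Rtot" and n_cond == 1:
        raise UnderIdentifiedError("epsilon and an Rtot scale are confounded (only epsilon*Rtot enters the response)")

    base = params.to_dict() | {"epsilon": spec.epsilon} | fixed

    def unpack(theta):
        vals = dict(base)
        for i, name in enumerate(free):
            vals[name] = math.exp(theta[i])
        scales = {conditions[0]: 1.0} if free_scales else {c: 1.0 for c in conditions}
        for j, c in enumerate(conditions[1:] if free_scales else []):
            scales[c] = math.exp(theta[len(free) + j])
        return vals, scales

    data_x, data_y, data_c = [], [], []
    for c in conditions:
        d = datasets[c]
        mask = d["dose_M"] > 0
        data_x.append(d.loc[mask, "dose_M"].to_numpy(dtype=float))
        data_y.append(d.loc[mask, "response"].to_numpy(dtype=float))
        data_c.append(c)

    def predict(vals, scales, c, doses):
        p = EquilibriumParams(**{k: vals[k] for k in ("Ka", "Kc", "Kd", "alpha", "beta", "gamma", "delta")})
        sp = ResponseSpec(coefficients=spec.coefficients, epsilon=vals["epsilon"])
        m = milieu
        if scale_target == "Rtot":
            m = m.replace(Rtot=milieu.Rtot * scales[c])
        else:
            m = m.replace(C=milieu.C * scales[c])
        return np.array([response_at(p, m, sp, float(x)) for x in doses])

    def resid(theta):
        vals, scales = unpack(theta)
        rs = [predict(vals, scales, c, x) - y for c, x, y in zip(data_c, data_x, data_y)]
        return np.concatenate(rs)

    theta0 = np.zeros(n_free)
    for i, name in enumerate(free):
        theta0[i] = math.log(base[name])
    if free_scales:
        theta0[len(free):] = math.log(0.5)

    if n_free == 0:
        raise ValueError("declare at least one free parameter or free_scales")
    sol = optimize.least_squares(resid, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError("mechanistic fit did not converge", last_iterate=sol.x)

    vals, scales = unpack(sol.x)
    n = sum(y.size for y in data_y)
    dof = max(n - n_free, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    JTJ = sol.jac.T @ sol.jac
    # identifiability: near-null singular directions of the Jacobian
    u, sv, vt = np.linalg.svd(sol.jac, full_matrices=False)
    names = list(free) + ([f"scale[{c}]" for c in conditions[1:]] if free_scales else [])
    weak = []
    for i, s in enumerate(sv):
        if s < 1e-8 * sv.max():
            combo = {names[j]: float(vt[i, j]) for j in range(len(names)) if abs(vt[i, j]) > 0.1}
            weak.append(combo)
    if weak:
        raise UnderIdentifiedError(
            f"data do not constrain the log-parameter combination(s) {weak}; fix one member of each"
        )
    try:
        cov = s2 * np.linalg.inv(JTJ)
        ses_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses_log = np.full(n_free, np.nan)

    # delta method back to the natural scale: SE(x) = x * SE(log x)
    est = {name: vals[name] for name in free}
    se = {name: est[name] * ses_log[i] for i, name in enumerate(free)}
    scale_se = {}
    if free_scales:
        for j, c in enumerate(conditions[1:]):
            scale_se[c] = scales[c] * ses_log[len(free) + j]
        scale_se[conditions[0]] = 0.0
    ident = {
        "free": names,
        "n_conditions": n_cond,
        "singular_values": [float(s) for s in sv],
    }
    return MechanisticFit(
        estimates=est,
        se=se,
        scales=scales,
        scale_se=scale_se,
        residual_sd=float(math.sqrt(s2)),
        n_obs=n,
        converged=True,
        identifiability=ident,
    )
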