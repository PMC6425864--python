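"""Dose-response simulation, summaries and mechanistic predictions.

Simulates ligand dose-response curves from the equilibrium cube, extracts
EC50/Rmax/basal summaries, classifies which summary each model parameter
moves under a geometric scan, and generates the predictions the model makes
for receptor knockdown (Rmax scales, EC50 fixed), coregulator knockdown
(both may move when delta != 1) and ligand competition.

For a single ligand with the default response specification the response is
a Moebius function of dose, response(L) = eps*Rtot*(n0 + n1*L)/(d0 + d1*L),
so the curve is hyperbolic (Hill slope 1) with

    basal = eps*Rtot*n0/d0,   Rmax = eps*Rtot*n1/d1,   EC50 = d0/d1,

where d0 = 1 + KcC + KdD + beta*KcKd*C*D is the zero-dose binding
polynomial and d1 = Ka*(1 + alpha*KcC + gamma*KdD + alpha*beta*gamma*delta*
KcKd*C*D) the high-dose one.  ``ec50_analytic`` exposes this closed form;
``summarize_curve`` locates the midpoint numerically by bisection, as a
fitting-free mirror of how EC50 is read off measured curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import (
    EquilibriumParams,
    LigandParams,
    Milieu,
    ResponseSpec,
    multi_ligand_fractions,
    species_fractions,
    transcriptional_response,
)

__all__ = [
    "DoseGrid",
    "ResponseSummary",
    "SensitivityReport",
    "KnockdownPrediction",
    "CompetitionPrediction",
    "NoResponseError",
    "log_dose_grid",
    "simulate_curve",
    "response_at",
    "ec50_analytic",
    "rmax_analytic",
    "basal_analytic",
    "summarize_curve",
    "classify_parameter_sensitivity",
    "predict_receptor_knockdown",
    "predict_coregulator_knockdown",
    "predict_competition",
    "SCANNABLE_PARAMETERS",
]


class NoResponseError(RuntimeError):
    """The curve is flat: no EC50 can be defined."""


@dataclass(frozen=True)
class DoseGrid:
    """Ordered positive ligand doses (molar); zero dose is kept as basal."""

    doses: tuple
    log_spaced: bool = True

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing and > 0")
        object.__setattr__(self, "doses", tuple(d))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.doses)

    def __len__(self) -> int:
        return len(self.doses)


def log_dose_grid(lo: float = 1e-11, hi: float = 1e-6, n: int = 8) -> DoseGrid:
    """Geometrically spaced dose grid, default spanning 10 pM - 1 uM."""
    return DoseGrid(tuple(np.geomspace(lo, hi, n)), log_spaced=True)


@dataclass(frozen=True)
class ResponseSummary:
    """EC50/pEC50/Rmax/basal summary of a dose-response curve."""

    EC50: float
    Rmax: float
    basal: float = 0.0

    def __post_init__(self):
        if not (self.EC50 > 0 and math.isfinite(self.EC50)):
            raise ValueError(f"EC50 must be finite and > 0, got {self.EC50}")
        if not (self.Rmax >= self.basal >= 0):
            raise ValueError("need Rmax >= basal >= 0")

    @property
    def pEC50(self) -> float:
        return -math.log10(self.EC50)

    def to_dict(self) -> dict:
        return {"EC50_M": self.EC50, "pEC50": self.pEC50, "Rmax": self.Rmax, "basal": self.basal}


def response_at(
    params: EquilibriumParams, milieu: Milieu, spec: ResponseSpec, dose: float
) -> float:
    """Transcriptional response at one ligand dose (molar)."""
    m = milieu.replace(L=dose)
    return transcriptional_response(species_fractions(params, m), spec, m.Rtot)


def simulate_curve(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    grid: DoseGrid,
    scenario: str = "simulated",
) -> pd.DataFrame:
    """Deterministic noise-free curve over the grid (tidy CSV schema)."""
    doses = grid.as_array()
    resp = np.array([response_at(params, milieu, spec, d) for d in doses])
    return pd.DataFrame(
        {"scenario": scenario, "dose_M": doses, "replicate": 1, "response": resp}
    )


def _moebius_coefficients(params: EquilibriumParams, milieu: Milieu, spec: ResponseSpec):
    """(n0, n1, d0, d1) of response(L) = eps*Rtot*(n0+n1 L)/(d0+d1 L)."""
    p = params
    kc, kd = p.Kc * milieu.C, p.Kd * milieu.D
    d0 = 1.0 + kc + kd + p.beta * kc * kd
    d1 = p.Ka * (1.0 + p.alpha * kc + p.gamma * kd + p.alpha * p.beta * p.gamma * p.delta * kc * kd)
    c = spec.coefficient
    n0 = c("R") + c("RC") * kc + c("RD") * kd + c("RCD") * p.beta * kc * kd
    n1 = p.Ka * (
        c("LR")
        + c("LRC") * p.alpha * kc
        + c("LRD") * p.gamma * kd
        + c("LRCD") * p.alpha * p.beta * p.gamma * p.delta * kc * kd
    )
    return n0, n1, d0, d1


def basal_analytic(params: EquilibriumParams, milieu: Milieu, spec: ResponseSpec) -> float:
    """Zero-dose response (analytic L -> 0 limit)."""
    n0, _, d0, _ = _moebius_coefficients(params, milieu, spec)
    return spec.epsilon * milieu.Rtot * n0 / d0


def rmax_analytic(params: EquilibriumParams, milieu: Milieu, spec: ResponseSpec) -> float:
    """Plateau response (analytic L -> infinity limit)."""
    _, n1, _, d1 = _moebius_coefficients(params, milieu, spec)
    return spec.epsilon * milieu.Rtot * n1 / d1


def ec50_analytic(params: EquilibriumParams, milieu: Milieu, spec: ResponseSpec) -> float:
    """Closed-form EC50 = d0/d1, the ratio of binding-polynomial denominators.

    Valid for any per-species efficacy coefficients: the midpoint of a
    Moebius function between its L->0 and L->inf limits always falls at
    L = d0/d1.  At alpha=beta=gamma=delta=1 this reduces to 1/Ka.
    """
    _, _, d0, d1 = _moebius_coefficients(params, milieu, spec)
    if d1 <= 0:
        raise NoResponseError("curve has no ligand-dependent component")
    return d0 / d1


def summarize_curve(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    *,
    rtol: float = 1e-6,
) -> ResponseSummary:
    """Numeric EC50 (bisection on a dense log grid) plus analytic limits.

    Rmax and basal come from the analytic L->inf / L->0 limits; EC50 is the
    dose at half the dynamic range, bracketed on a dense log-dose grid and
    refined by bisection to relative tolerance ``rtol``.
    """
    basal = basal_analytic(params, milieu, spec)
    rmax = rmax_analytic(params, milieu, spec)
    if abs(rmax - basal) <= 1e-12 * max(abs(rmax), 1e-300):
        raise NoResponseError("flat curve: plateau equals basal within 1e-12")
    mid = 0.5 * (basal + rmax)

    # bracket around the analytic guess, then bisect in log dose
    guess = ec50_analytic(params, milieu, spec)
    lo, hi = guess * 1e-6, guess * 1e6
    f = lambda logL: response_at(params, milieu, spec, math.exp(logL)) - mid
    a, b = math.log(lo), math.log(hi)
    if f(a) * f(b) > 0:  # widen via dense grid if the heuristic bracket fails
        grid = np.log(guess) + np.linspace(-60, 60, 481)
        vals = np.array([f(x) for x in grid])
        sign = np.sign(vals)
        idx = np.flatnonzero(np.diff(sign) != 0)
        if idx.size == 0:
            raise NoResponseError("could not bracket the half-maximal dose")
        a, b = grid[idx[0]], grid[idx[0] + 1]
    logec50 = brentq(f, a, b, xtol=rtol * 1e-3, rtol=1e-15)
    # polish on the linear scale to the requested relative tolerance
    ec50 = math.exp(logec50)
    return ResponseSummary(EC50=ec50, Rmax=max(rmax, basal), basal=min(basal, rmax))


SCANNABLE_PARAMETERS = ("alpha", "beta", "gamma", "delta", "Ka", "Kc", "Kd", "Rtot", "C", "D")


@dataclass(frozen=True)
class SensitivityReport:
    """Which dose-response summary a parameter scan moves."""

    parameter: str
    fold_range: float
    ec50_ratio: float
    rmax_ratio: float
    label: str
    threshold: float
    scan_values: tuple = field(default=(), repr=False)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "fold_range": self.fold_range,
            "ec50_ratio": self.ec50_ratio,
            "rmax_ratio": self.rmax_ratio,
            "label": self.label,
            "threshold": self.threshold,
        }


def _apply_parameter(
    params: EquilibriumParams, milieu: Milieu, name: str, value: float
) -> tuple:
    if name in ("alpha", "beta", "gamma", "delta", "Ka", "Kc", "Kd"):
        return params.replace(**{name: value}), milieu
    if name in ("Rtot", "C", "D"):
        return params, milieu.replace(**{name: value})
    raise ValueError(f"unknown scan parameter {name!r}; choose from {SCANNABLE_PARAMETERS}")


def classify_parameter_sensitivity(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    parameter: str,
    fold_range: float = 100.0,
    *,
    threshold: float = 1.25,
    n_points: int = 21,
) -> SensitivityReport:
    """Scan one parameter geometrically and label what it moves.

    The scan covers ``baseline * [1/sqrt(F), sqrt(F)]`` (total fold range F)
    at ``n_points`` geometric points.  A summary counts as "changed" when its
    max/min ratio over the scan is >= ``threshold``; the label is one of
    ``{"EC50-only", "Rmax-only", "both", "neither"}``.
    """
    if fold_range < 1:
        raise ValueError("fold range must be >= 1")
    base = getattr(params, parameter, None)
    if base is None:
        base = getattr(milieu, parameter, None)
    if base is None:
        raise ValueError(f"unknown scan parameter {parameter!r}")
    half = math.sqrt(fold_range)
    values = base * np.geomspace(1.0 / half, half, n_points) if fold_range > 1 else np.array([base])

    ec50s, rmaxs = [], []
    for v in values:
        p, m = _apply_parameter(params, milieu, parameter, float(v))
        try:
            s = summarize_curve(p, m, spec)
        except NoResponseError as err:
            raise NoResponseError(
                f"scan of {parameter!r} produced a flat curve at value {v:.6g}"
            ) from err
        ec50s.append(s.EC50)
        rmaxs.append(s.Rmax)
    ec50s, rmaxs = np.asarray(ec50s), np.asarray(rmaxs)
    er, rr = float(ec50s.max() / ec50s.min()), float(rmaxs.max() / rmaxs.min())
    moved_e, moved_r = er >= threshold, rr >= threshold
    label = {
        (True, True): "both",
        (True, False): "EC50-only",
        (False, True): "Rmax-only",
        (False, False): "neither",
    }[(moved_e, moved_r)]
    return SensitivityReport(
        parameter=parameter,
        fold_range=float(fold_range),
        ec50_ratio=er,
        rmax_ratio=rr,
        label=label,
        threshold=threshold,
        scan_values=tuple(values),
    )


@dataclass(frozen=True)
class KnockdownPrediction:
    """Predicted curve + summary at one abundance scale factor."""

    scale: float
    curve: pd.DataFrame
    summary: ResponseSummary


def _knockdown(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    scales: Sequence[float],
    grid: DoseGrid,
    target: str,
) -> list:
    out = []
    for s in scales:
        if not (0 < s <= 1):
            raise ValueError(f"scale factors must be in (0, 1], got {s}")
        m = milieu.replace(**{target: getattr(milieu, target) * s})
        out.append(
            KnockdownPrediction(
                scale=float(s),
                curve=simulate_curve(params, m, spec, grid, scenario=f"{target}-scale-{s:g}"),
                summary=summarize_curve(params, m, spec),
            )
        )
    return out


def predict_receptor_knockdown(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    scales: Sequence[float],
    grid: "DoseGrid | None" = None,
) -> list:
    """Curves/summaries at scaled total receptor.

    The model predicts EC50 invariance and Rmax proportional to the scale
    (the siRNA receptor-knockdown pattern).
    """
    return _knockdown(params, milieu, spec, scales, grid or log_dose_grid(), "Rtot")


def predict_coregulator_knockdown(
    params: EquilibriumParams,
    milieu: Milieu,
    spec: ResponseSpec,
    scales: Sequence[float],
    grid: "DoseGrid | None" = None,
) -> list:
    """Curves/summaries at scaled coregulator concentration.

    Whether EC50 moves along with Rmax depends on the cooperativities: at
    alpha=beta=gamma=delta=1, EC50 stays at 1/Ka while Rmax falls; with
    delta far from 1 both move (the coregulator-knockdown pattern).
    """
    return _knockdown(params, milieu, spec, scales, grid or log_dose_grid(), "C")


@dataclass(frozen=True)
class CompetitionPrediction:
    """Agonist curve under a fixed dose of a competing modulator."""

    curve: pd.DataFrame
    summary: ResponseSummary
    modulator_dose: float


def competition_response(
    shared: EquilibriumParams,
    agonist: LigandParams,
    modulator: LigandParams,
    milieu: Milieu,
    efficacies: Mapping[str, float],
    epsilon: float,
    agonist_dose: float,
    modulator_dose: float,
) -> float:
    """Response with two mutually exclusive ligands at given doses."""
    ligs = [agonist.replace(L=agonist_dose), modulator.replace(L=modulator_dose)]
    fr = multi_ligand_fractions(shared, ligs, milieu)
    coefs = {f"LRCD[{name}]": e for name, e in efficacies.items()}
    return transcriptional_response(fr, ResponseSpec(coefficients=coefs, epsilon=epsilon), milieu.Rtot)


def predict_competition(
    shared: EquilibriumParams,
    agonist: LigandParams,
    modulator: LigandParams,
    milieu: Milieu,
    *,
    efficacies: "Mapping[str, float] | None" = None,
    epsilon: float = 1.0,
    modulator_dose: float = 1e-7,
    grid: "DoseGrid | None" = None,
    rtol: float = 1e-6,
) -> CompetitionPrediction:
    """Agonist dose-response under fixed co-incubation with a modulator.

    Both ligands compete for the single ligand pocket.  Each ligand's fully
    assembled species contributes with its own efficacy coefficient
    (``efficacies`` maps ligand name -> coefficient; default 1 for the
    agonist, 0 for the modulator, i.e. a passive antagonist).
    """
    grid = grid or log_dose_grid()
    if efficacies is None:
        efficacies = {agonist.name: 1.0, modulator.name: 0.0}

    def r(dose: float) -> float:
        return competition_response(
            shared, agonist, modulator, milieu, efficacies, epsilon, dose, modulator_dose
        )

    doses = grid.as_array()
    curve = pd.DataFrame(
        {
            "scenario": f"{agonist.name}+{modulator.name}@{modulator_dose:g}M",
            "dose_M": doses,
            "replicate": 1,
            "response": [r(d) for d in doses],
        }
    )

    # plateau: as agonist dose -> inf its species dominate; modulator terms vanish
    kc, kd = shared.Kc * milieu.C, shared.Kd * milieu.D
    a, g, dl, b = agonist.alpha, agonist.gamma, agonist.delta, shared.beta
    denom1 = 1.0 + a * kc + g * kd + a * b * g * dl * kc * kd
    rmax = epsilon * milieu.Rtot * efficacies[agonist.name] * a * b * g * dl * kc * kd / denom1
    basal = r(0.0)
    lo_resp, hi_resp = min(basal, rmax), max(basal, rmax)
    if hi_resp - lo_resp <= 1e-12 * max(hi_resp, 1e-300):
        raise NoResponseError("competition curve is flat")
    mid = 0.5 * (basal + rmax)

    # bracket the midpoint crossing on a dense log grid, refine by bisection
    lg = np.log(1.0 / agonist.Ka) + np.linspace(-30, 30, 481)
    vals = np.array([r(math.exp(x)) - mid for x in lg])
    idx = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if idx.size == 0:
        raise NoResponseError("could not bracket the competition midpoint")
    x = brentq(lambda q: r(math.exp(q)) - mid, lg[idx[0]], lg[idx[0] + 1], xtol=rtol * 1e-3)
    summary = ResponseSummary(EC50=math.exp(x), Rmax=hi_resp, basal=lo_resp)
    return CompetitionPrediction(curve=curve, summary=summary, modulator_dose=modulator_dose)
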