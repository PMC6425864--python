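"""Equilibrium core of the quaternary receptor model.

A nuclear receptor R binds three partners: a ligand L, a coregulator C
(an LXXLL NR-box motif) and a DNA response element D.  At equilibrium the
receptor is partitioned over the eight species on the corners of a cube,

    R, LR, RC, RD, LRC, LRD, RCD, LRCD,

governed by three association constants (Ka for ligand, Kc for coregulator,
Kd for DNA, all per molar) and four dimensionless cooperativity factors:
alpha (ligand <-> coregulator), beta (coregulator <-> DNA), gamma
(ligand <-> DNA) and delta, the third-order term expressing how the joint
effect of any two binding events depends on the third.

The statistical weight of each species relative to free R is the product of
K*concentration factors for each bound partner times the cooperativity
factors for each pair of bound partners, with the fully occupied species
additionally carrying delta:

    w(R)    = 1
    w(LR)   = Ka*L
    w(RC)   = Kc*C
    w(RD)   = Kd*D
    w(LRC)  = alpha * Ka*Kc * L*C
    w(LRD)  = gamma * Ka*Kd * L*D
    w(RCD)  = beta  * Kc*Kd * C*D
    w(LRCD) = alpha*beta*gamma*delta * Ka*Kc*Kd * L*C*D

This is the cubic-ternary-complex convention; it is isolated in
:func:`statistical_weights` so an alternative convention can be swapped in.

Transcription is attributed to the fully assembled complex LRCD by default
(optionally also to the apo complex RCD, for ligand-independent activity),
scaled by ``epsilon * Rtot`` to map occupancy into fold-induction units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SPECIES",
    "EquilibriumParams",
    "Milieu",
    "SpeciesDistribution",
    "ResponseSpec",
    "LigandParams",
    "ConservedState",
    "WeightOverflowError",
    "ConvergenceError",
    "statistical_weights",
    "species_fractions",
    "solve_conserved",
    "multi_ligand_fractions",
    "transcriptional_response",
]

#: Canonical species order of the cube.
SPECIES = ("R", "LR", "RC", "RD", "LRC", "LRD", "RCD", "LRCD")

#: Largest statistical weight handled in linear arithmetic; beyond this the
#: fraction computation switches to log space.
_LINEAR_WEIGHT_MAX = 1e300


class WeightOverflowError(OverflowError):
    """A statistical weight overflowed for a named species."""

    def __init__(self, species: str):
        self.species = species
        super().__init__(
            f"statistical weight of species {species!r} overflows double "
            "precision; the parameter/concentration combination is unusable"
        )


class ConvergenceError(RuntimeError):
    """The conserved-totals solver failed to converge."""

    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (max relative residual {residual:.3e})")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class EquilibriumParams:
    """Association constants (per molar) and cooperativity factors."""

    Ka: float
    Kc: float
    Kd: float
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0

    def __post_init__(self):
        for name in ("Ka", "Kc", "Kd"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"{name} must be finite and > 0, got {v}")
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")

    def replace(self, **kw) -> "EquilibriumParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("Ka", "Kc", "Kd", "alpha", "beta", "gamma", "delta")}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EquilibriumParams":
        return cls(**{k: float(d[k]) for k in ("Ka", "Kc", "Kd", "alpha", "beta", "gamma", "delta") if k in d})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class Milieu:
    """Free concentrations (molar) of the partners and total receptor."""

    L: float
    C: float
    D: float
    Rtot: float = 1.0

    def __post_init__(self):
        for name in ("L", "C", "D", "Rtot"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")

    def replace(self, **kw) -> "Milieu":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("L", "C", "D", "Rtot")}


@dataclass(frozen=True)
class SpeciesDistribution:
    """Equilibrium fraction of total receptor in each of the eight species."""

    fractions: tuple

    def __post_init__(self):
        _require(len(self.fractions) == len(SPECIES), "need one fraction per species")

    def __getitem__(self, species: str) -> float:
        return self.fractions[SPECIES.index(species)]

    def as_dict(self) -> dict:
        return dict(zip(SPECIES, self.fractions))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)


@dataclass(frozen=True)
class ResponseSpec:
    """Maps the species distribution to a transcriptional response.

    ``coefficients`` assigns a per-species efficacy (default: 1 for LRCD,
    0 for everything else); a nonzero RCD coefficient models basal,
    ligand-independent transcription by the apo receptor complex.
    ``epsilon`` scales receptor-concentration-weighted occupancy into
    fold-induction units.
    """

    coefficients: Mapping[str, float] = field(default_factory=lambda: {"LRCD": 1.0})
    epsilon: float = 1.0

    def __post_init__(self):
        _require(math.isfinite(self.epsilon) and self.epsilon > 0, "epsilon must be > 0")
        for k, v in self.coefficients.items():
            _require(math.isfinite(v) and v >= 0, f"coefficient for {k} must be >= 0, got {v}")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def coefficient(self, species: str) -> float:
        return self.coefficients.get(species, 0.0)

    def to_dict(self) -> dict:
        return {"coefficients": dict(self.coefficients), "epsilon": self.epsilon}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponseSpec":
        return cls(coefficients=d.get("coefficients", {"LRCD": 1.0}), epsilon=float(d.get("epsilon", 1.0)))


def statistical_weights(params: EquilibriumParams, milieu: Milieu) -> np.ndarray:
    """Statistical weight of each species relative to free receptor.

    Returns the eight weights in :data:`SPECIES` order.  Raises
    :class:`WeightOverflowError` naming the first species whose weight
    exceeds double precision.
    """
    L, C, D = milieu.L, milieu.C, milieu.D
    p = params
    kl, kc, kd = p.Ka * L, p.Kc * C, p.Kd * D
    w = np.array(
        [
            1.0,
            kl,
            kc,
            kd,
            p.alpha * kl * kc,
            p.gamma * kl * kd,
            p.beta * kc * kd,
            p.alpha * p.beta * p.gamma * p.delta * kl * kc * kd,
        ]
    )
    if not np.all(np.isfinite(w)):
        bad = int(np.flatnonzero(~np.isfinite(w))[0])
        raise WeightOverflowError(SPECIES[bad])
    return w


def _log_weights(params: EquilibriumParams, milieu: Milieu) -> np.ndarray:
    """Log statistical weights; -inf for species with an absent partner."""
    with np.errstate(divide="ignore"):
        lL, lC, lD = (np.log(x) for x in (milieu.L, milieu.C, milieu.D))
        la, lb, lg, ld = (np.log(x) for x in (params.alpha, params.beta, params.gamma, params.delta))
        lKa, lKc, lKd = (np.log(x) for x in (params.Ka, params.Kc, params.Kd))
    kl, kc, kd = lKa + lL, lKc + lC, lKd + lD
    return np.array(
        [0.0, kl, kc, kd, la + kl + kc, lg + kl + kd, lb + kc + kd, la + lb + lg + ld + kl + kc + kd]
    )


def _fractions_array(params: EquilibriumParams, milieu: Milieu) -> np.ndarray:
    lw = _log_weights(params, milieu)
    if np.max(lw) <= np.log(_LINEAR_WEIGHT_MAX):
        w = statistical_weights(params, milieu)
        return w / w.sum()
    # log-space path: species with -inf weight have exactly zero fraction
    finite = np.isfinite(lw)
    out = np.zeros_like(lw)
    m = lw[finite].max()
    e = np.exp(lw[finite] - m)
    out[finite] = e / e.sum()
    return out


def species_fractions(params: EquilibriumParams, milieu: Milieu) -> SpeciesDistribution:
    """Equilibrium fractions of the eight species (partners in excess).

    Free partner concentrations are taken equal to totals (no depletion);
    use :func:`solve_conserved` to validate that assumption.
    """
    return SpeciesDistribution(tuple(_fractions_array(params, milieu)))


@dataclass(frozen=True)
class ConservedState:
    """Solution of the conserved-totals problem (all molar)."""

    free: dict  # free L, C, D, R
    species: dict  # molar concentration of each of the eight species
    residual: float  # max relative mass-balance residual

    def fractions(self) -> SpeciesDistribution:
        rtot = sum(self.species.values())
        return SpeciesDistribution(tuple(self.species[s] / rtot for s in SPECIES))


# which partners each species consumes (L, C, D)
_CONTAINS = {
    "R": (0, 0, 0), "LR": (1, 0, 0), "RC": (0, 1, 0), "RD": (0, 0, 1),
    "LRC": (1, 1, 0), "LRD": (1, 0, 1), "RCD": (0, 1, 1), "LRCD": (1, 1, 1),
}
_L_MASK = np.array([_CONTAINS[s][0] for s in SPECIES], dtype=float)
_C_MASK = np.array([_CONTAINS[s][1] for s in SPECIES], dtype=float)
_D_MASK = np.array([_CONTAINS[s][2] for s in SPECIES], dtype=float)


def solve_conserved(
    params: EquilibriumParams,
    totals: Mapping[str, float],
    *,
    rtol: float = 1e-9,
    max_iter: int = 10_000,
) -> ConservedState:
    """Solve the equilibrium with conserved totals of L, C, D and R.

    ``totals`` maps ``{"L": Ltot, "C": Ctot, "D": Dtot, "R": Rtot}``.  Uses a
    damped multiplicative fixed point on the free partner concentrations with
    a bounded least-squares root-finder as fallback.  Convergence is declared
    at maximum relative mass-balance residual ``rtol``.
    """
    Lt, Ct, Dt, Rt = (float(totals[k]) for k in ("L", "C", "D", "R"))
    for name, v in (("L", Lt), ("C", Ct), ("D", Dt), ("R", Rt)):
        _require(v >= 0 and math.isfinite(v), f"total {name} must be >= 0 and finite")
    _require(Rt > 0, "total receptor must be > 0")

    def bound_and_residual(free: np.ndarray):
        l, c, d = free
        w = statistical_weights(params, Milieu(L=l, C=c, D=d, Rtot=Rt))
        r = Rt / w.sum()
        conc = r * w
        bl, bc, bd = (conc * _L_MASK).sum(), (conc * _C_MASK).sum(), (conc * _D_MASK).sum()
        res = np.array(
            [
                (l + bl - Lt) / max(Lt, Rt),
                (c + bc - Ct) / max(Ct, Rt),
                (d + bd - Dt) / max(Dt, Rt),
            ]
        )
        return np.array([bl, bc, bd]), res, r, conc

    totals_vec = np.array([Lt, Ct, Dt])
    active = totals_vec > 0
    free = totals_vec.copy()  # start from no-depletion guess

    converged = False
    res = np.full(3, np.inf)
    for _ in range(max_iter):
        bound, res, r, conc = bound_and_residual(free)
        if (not active.any()) or np.max(np.abs(res[active])) < rtol:
            converged = True
            break
        # multiplicative update: free <- free * total / (free + bound)
        with np.errstate(invalid="ignore", divide="ignore"):
            upd = np.where(active, totals_vec / np.maximum(free + bound, 1e-300), 1.0)
        free = np.where(active, free * upd, 0.0)

    if not converged:
        # fallback: bounded least squares on log free concentrations
        act = np.flatnonzero(active)
        if act.size:
            def f(logx):
                fr = free.copy()
                fr[act] = np.exp(logx)
                _, rr, _, _ = bound_and_residual(fr)
                return rr[act]

            x0 = np.log(np.maximum(free[act], 1e-30 * totals_vec[act]))
            sol = least_squares(f, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            free[act] = np.exp(sol.x)
        bound, res, r, conc = bound_and_residual(free)
        if active.any() and np.max(np.abs(res[active])) >= rtol:
            raise ConvergenceError(
                "conserved-totals solver did not converge", float(np.max(np.abs(res[active])))
            )

    bound, res, r, conc = bound_and_residual(free)
    return ConservedState(
        free={"L": free[0], "C": free[1], "D": free[2], "R": r},
        species=dict(zip(SPECIES, conc)),
        residual=float(np.max(np.abs(res[active]))) if active.any() else 0.0,
    )


@dataclass(frozen=True)
class LigandParams:
    """Per-ligand constants for the multi-ligand competition model."""

    name: str
    Ka: float
    alpha: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    L: float = 0.0

    def __post_init__(self):
        _require(math.isfinite(self.Ka) and self.Ka > 0, "Ka must be finite and > 0")
        for f in ("alpha", "gamma", "delta"):
            v = getattr(self, f)
            _require(math.isfinite(v) and v >= 0, f"{f} must be finite and >= 0")
        _require(math.isfinite(self.L) and self.L >= 0, "L must be finite and >= 0")

    def replace(self, **kw) -> "LigandParams":
        return replace(self, **kw)


def multi_ligand_species(ligands: Sequence[LigandParams]) -> list:
    """Ordered species labels: ligand-free corner plus per-ligand corners."""
    out = ["R", "RC", "RD", "RCD"]
    for lig in ligands:
        out += [f"LR[{lig.name}]", f"LRC[{lig.name}]", f"LRD[{lig.name}]", f"LRCD[{lig.name}]"]
    return out


def multi_ligand_fractions(
    shared: EquilibriumParams,
    ligands: Sequence[LigandParams],
    milieu: Milieu,
) -> dict:
    """Species fractions with several ligands competing for one site.

    ``shared`` supplies Kc, Kd and beta (its Ka/alpha/gamma/delta are
    ignored); each ligand brings its own Ka, alpha, gamma, delta and
    concentration ``L``.  Ligands bind mutually exclusively, so the
    distribution spans the four ligand-free species plus four species per
    ligand.  Fractions sum to 1; a ligand at zero concentration contributes
    exactly-zero fractions, marginalizing to the remaining-ligand model.
    """
    _require(len(ligands) >= 1, "need at least one ligand")
    names = [l.name for l in ligands]
    _require(len(set(names)) == len(names), f"duplicate ligand identifiers: {names}")

    kc, kd = shared.Kc * milieu.C, shared.Kd * milieu.D
    b = shared.beta
    weights = [1.0, kc, kd, b * kc * kd]
    for lig in ligands:
        kl = lig.Ka * lig.L
        weights += [
            kl,
            lig.alpha * kl * kc,
            lig.gamma * kl * kd,
            lig.alpha * b * lig.gamma * lig.delta * kl * kc * kd,
        ]
    w = np.asarray(weights)
    if not np.all(np.isfinite(w)):
        bad = int(np.flatnonzero(~np.isfinite(w))[0])
        raise WeightOverflowError(multi_ligand_species(ligands)[bad])
    fr = w / w.sum()
    return dict(zip(multi_ligand_species(ligands), fr))


def transcriptional_response(
    dist: "SpeciesDistribution | Mapping[str, float]",
    spec: ResponseSpec,
    Rtot: float,
) -> float:
    """Response in fold-induction units: epsilon * Rtot * sum(coef_s * f_s).

    Accepts the single-ligand :class:`SpeciesDistribution` or the extended
    mapping returned by :func:`multi_ligand_fractions` (coefficient keys then
    use the extended labels, e.g. ``"LRCD[DEX]"``).
    """
    _require(math.isfinite(Rtot) and Rtot >= 0, "Rtot must be >= 0")
    fr = dist.as_dict() if isinstance(dist, SpeciesDistribution) else dict(dist)
    return spec.epsilon * Rtot * sum(spec.coefficient(s) * f for s, f in fr.items())
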