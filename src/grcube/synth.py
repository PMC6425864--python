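"""Synthetic-data generators for every pipeline input.

Each generator is a bit-reproducible function of (truth, design, seed) and
returns the dataset in the exact tidy schema the analysis modules consume,
together with a truth dictionary (written as a JSON sidecar by the
pipeline) that closes the loop for recovery tests.

Noise families match each measurement's support: Gaussian with a
coefficient of variation (floored at zero response) for qPCR fold-induction
readouts, lognormal for array fluorescence (non-negative, multiplicative
error), and additive Gaussian on Cp cycles.  Default designs mirror the
study conditions the pipeline emulates: 8 doses spanning 10 pM - 1 uM,
triplicates, 53-peptide panels probed with 1 nM receptor and 1 uM ligand,
and triplicate qPCR plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coregulator import Peptide, PeptidePanel, binding_signal
from .dose_response import DoseGrid, competition_response, log_dose_grid, response_at
from .equilibrium import EquilibriumParams, LigandParams, Milieu, ResponseSpec
from .fitting import logistic4

__all__ = [
    "SyntheticConfig",
    "gen_dose_response",
    "gen_knockdown_series",
    "gen_competition",
    "gen_marconi",
    "gen_qpcr_plate",
    "default_panel",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Seed, replicate counts and per-data-kind noise levels."""

    seed: int = 0
    n_replicates: int = 3
    dose_response_cv: float = 0.10  # Gaussian CV on responses, floored at 0
    array_cv: float = 0.10  # lognormal CV on fluorescence
    qpcr_cp_sd: float = 0.15  # additive Gaussian SD on Cp cycles

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        for f in ("dose_response_cv", "array_cv", "qpcr_cp_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _noisy_responses(
    mean: np.ndarray, cv: float, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_rep, n_dose) Gaussian-CV noise around the truth, floored at 0."""
    m = np.asarray(mean, dtype=float)
    out = m[None, :] * (1.0 + cv * rng.standard_normal((n_rep, m.size)))
    return np.maximum(out, 0.0)


def _truth_curve(truth: Mapping, doses: np.ndarray) -> np.ndarray:
    """Expected response at each dose for a 4PL or mechanistic truth."""
    if "pEC50" in truth:  # 4PL truth
        return logistic4(
            doses,
            float(truth.get("bottom", 0.0)),
            float(truth["top"]),
            float(truth["pEC50"]),
            float(truth.get("hill", 1.0)),
        )
    params = EquilibriumParams.from_dict(truth["params"])
    milieu = Milieu(**truth["milieu"])
    spec = ResponseSpec.from_dict(truth.get("spec", {}))
    return np.array([response_at(params, milieu, spec, d) for d in doses])


def gen_dose_response(
    truth: Mapping,
    config: SyntheticConfig,
    *,
    grid: "DoseGrid | None" = None,
    condition: str = "truth",
) -> tuple:
    """Replicated dose-response dataset around a truth curve.

    ``truth`` is either 4PL parameters (``{"bottom", "top", "pEC50",
    "hill"}``, the study's fitted-parameter magnitudes: pEC50 near 9, Rmax
    tens of fold) or a mechanistic scenario (``{"params": ..., "milieu":
    ..., "spec": ...}``).  Returns ``(dataset, truth_record)``.
    """
    grid = grid or log_dose_grid()
    doses = grid.as_array()
    mean = _truth_curve(truth, doses)
    rng = config.rng()
    resp = _noisy_responses(mean, config.dose_response_cv, config.n_replicates, rng)
    rows = []
    for rep in range(config.n_replicates):
        for j, d in enumerate(doses):
            rows.append((condition, d, rep + 1, resp[rep, j]))
    df = pd.DataFrame(rows, columns=["condition", "dose_M", "replicate", "response"])
    record = {"truth": dict(truth), "seed": config.seed, "cv": config.dose_response_cv,
              "doses_M": list(doses), "condition": condition}
    return df, record


def gen_knockdown_series(
    truth: Mapping,
    scales: Sequence[float],
    config: SyntheticConfig,
    *,
    target: str = "Rtot",
    grid: "DoseGrid | None" = None,
) -> tuple:
    """Family of dose-response datasets at scaled receptor or coregulator.

    ``truth`` must be mechanistic; each scale in ``scales`` multiplies
    ``target`` ("Rtot" or "C") in the milieu.  Returns ``(dict of condition
    -> dataset, truth_record)``; each member gets an independent seed
    derived from the base seed so permuting the scale order permutes the
    outputs without coupling them.
    """
    if target not in ("Rtot", "C"):
        raise ValueError("target must be 'Rtot' or 'C'")
    datasets = {}
    for i, s in enumerate(scales):
        if not (0 < s <= 1):
            raise ValueError(f"scale factors must be in (0, 1], got {s}")
        milieu = dict(truth["milieu"])
        milieu[target] = milieu[target] * s
        member = {**truth, "milieu": milieu}
        # seed depends on the scale value, not its position in the list
        sub = config.replace(seed=(config.seed * 100_003 + hash_scale(s)) % (2**31))
        label = f"{target}-scale-{s:g}"
        df, _ = gen_dose_response(member, sub, grid=grid, condition=label)
        datasets[label] = df
    record = {"truth": dict(truth), "scales": list(map(float, scales)), "target": target,
              "seed": config.seed, "cv": config.dose_response_cv}
    return datasets, record


def hash_scale(s: float) -> int:
    """Stable small hash of a scale factor for per-member seeding."""
    return int.from_bytes(np.float64(s).tobytes(), "little") % 1_000_003


def gen_competition(
    shared: Mapping,
    agonist: Mapping,
    modulator: Mapping,
    modulator_dose: float,
    config: SyntheticConfig,
    *,
    milieu: "Mapping | None" = None,
    efficacies: "Mapping[str, float] | None" = None,
    epsilon: float = 1.0,
    grid: "DoseGrid | None" = None,
) -> tuple:
    """Agonist dose-response under fixed modulator co-incubation.

    ``agonist``/``modulator`` are LigandParams dictionaries (name, Ka,
    alpha, gamma, delta); ``shared`` supplies Kc, Kd, beta.  At
    ``modulator_dose`` = 0 the expectation equals the agonist-alone curve,
    so with the same seed the dataset is identical to
    :func:`gen_dose_response` of the agonist alone.
    """
    grid = grid or log_dose_grid()
    doses = grid.as_array()
    sh = EquilibriumParams.from_dict({"Ka": 1.0, **shared})
    ag = LigandParams(**agonist)
    mod = LigandParams(**modulator)
    mil = Milieu(**(dict(milieu) if milieu else {"L": 0.0, "C": 1e-9, "D": 1e-9, "Rtot": 1.0}))
    eff = dict(efficacies) if efficacies else {ag.name: 1.0, mod.name: 0.0}
    mean = np.array(
        [
            competition_response(sh, ag, mod, mil, eff, epsilon, float(d), float(modulator_dose))
            for d in doses
        ]
    )
    rng = config.rng()
    resp = _noisy_responses(mean, config.dose_response_cv, config.n_replicates, rng)
    rows = []
    label = f"{ag.name}+{mod.name}@{modulator_dose:g}M"
    for rep in range(config.n_replicates):
        for j, d in enumerate(doses):
            rows.append((label, d, rep + 1, resp[rep, j]))
    df = pd.DataFrame(rows, columns=["condition", "dose_M", "replicate", "response"])
    record = {
        "shared": dict(shared), "agonist": dict(agonist), "modulator": dict(modulator),
        "modulator_dose_M": float(modulator_dose), "efficacies": eff, "epsilon": epsilon,
        "milieu": mil.to_dict(), "seed": config.seed, "cv": config.dose_response_cv,
    }
    return df, record


def default_panel(
    seed: int = 0,
    n_peptides: int = 53,
    ligands: Sequence[str] = ("DEX", "RU486", "CYP"),
    *,
    n_dex_favored_cyp_unfavored: int = 7,
) -> PeptidePanel:
    """A 53-peptide panel with structured ligand modulation truth.

    Affinities Kc are log-uniform over 1e5 - 3e5 per molar (3 - 10 uM
    dissociation, the typical range of isolated LXXLL peptides), which at
    the default 1 uM peptide spot concentration keeps occupancy in the
    sensitive part of the isotherm so ligand modulation is visible.  A
    block of peptides is DEX-favored (alpha > 1) and CYP-unfavored
    (alpha < 1) — the pattern the array arm is designed to recover — with
    RU486 a weaker version of DEX; the remaining peptides are neutral
    (alpha = 1).
    """
    rng = np.random.default_rng(seed)
    kcs = 10.0 ** rng.uniform(5, math.log10(3e5), n_peptides)
    peptides = []
    for i in range(n_peptides):
        if i < n_dex_favored_cyp_unfavored:
            alphas = {"DEX": 4.0, "RU486": 1.8, "CYP": 0.3}
        elif i < n_dex_favored_cyp_unfavored + 5:
            alphas = {"DEX": 0.25, "RU486": 0.4, "CYP": 1.0}
        else:
            alphas = {lig: 1.0 for lig in ligands}
        peptides.append(
            Peptide(peptide_id=f"PEP{i:02d}_LxxLL", Kc=float(kcs[i]), alphas={l: alphas.get(l, 1.0) for l in ligands})
        )
    return PeptidePanel(tuple(peptides))


def gen_marconi(
    panel: PeptidePanel,
    ligands: Sequence[str],
    config: SyntheticConfig,
    *,
    Rtot: float = 1e-9,
    ligand_dose: float = 1e-6,
    peptide_conc: float = 1e-6,
    gain: float = 1e12,
    Ka: float = 1e8,
    vehicle: str = "vehicle",
) -> tuple:
    """Peptide-array dataset: vehicle plus one condition per ligand.

    Expected signals come from the DNA-free model (1 nM receptor, 1 uM
    ligand by default); replicate noise is lognormal with CV
    ``config.array_cv``.  Returns ``(dataset, truth_record)`` where the
    record holds every peptide's Kc and per-ligand alpha.
    """
    rng = config.rng()
    cv = config.array_cv
    sigma = math.sqrt(math.log1p(cv**2))  # lognormal sigma for a given CV
    rows = []
    for pep in panel:
        conds = {vehicle: (0.0, 1.0)}
        for lig in ligands:
            conds[lig] = (ligand_dose, pep.alpha(lig))
        for cond, (L, alpha) in conds.items():
            params = EquilibriumParams(Ka=Ka, Kc=pep.Kc, Kd=1.0, alpha=alpha)
            mean = binding_signal(params, L, peptide_conc, Rtot, gain)
            for rep in range(config.n_replicates):
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if cv > 0 else 1.0
                rows.append((pep.peptide_id, cond, rep + 1, mean * noise))
    df = pd.DataFrame(rows, columns=["peptide", "condition", "replicate", "signal"])
    record = {
        "panel": {p.peptide_id: {"Kc": p.Kc, "alphas": dict(p.alphas)} for p in panel},
        "Rtot_M": Rtot, "ligand_dose_M": ligand_dose, "peptide_conc_M": peptide_conc,
        "gain": gain, "Ka": Ka, "seed": config.seed, "cv": cv, "vehicle": vehicle,
    }
    return df, record


def gen_qpcr_plate(
    true_folds: Mapping[str, float],
    config: SyntheticConfig,
    *,
    eff_target: float = 2.0,
    eff_reference: float = 2.0,
    target: str = "target",
    reference: str = "reference",
    baseline_cp: "Mapping[str, float] | None" = None,
    control: str = "control",
) -> tuple:
    """qPCR plate whose expected Cp values invert to the true folds.

    ``true_folds`` maps experimental condition -> fold vs the control.  The
    reference gene is stable across conditions; the target gene's
    experimental-group Cp is shifted by dCp = ln(fold)/ln(eff_target)
    below the control.  Gaussian Cp noise with SD ``config.qpcr_cp_sd``.
    """
    for cond, f in true_folds.items():
        if not f > 0:
            raise ValueError(f"fold for {cond!r} must be > 0")
    for name, e in (("target", eff_target), ("reference", eff_reference)):
        if not e > 1:
            raise ValueError(f"{name} efficiency must be > 1")
    base = dict(baseline_cp or {target: 26.0, reference: 18.0})
    rng = config.rng()
    sd = config.qpcr_cp_sd
    rows = []
    conditions = [control] + list(true_folds)
    for gene in (target, reference):
        for cond in conditions:
            if gene == target and cond != control:
                dcp = math.log(true_folds[cond]) / math.log(eff_target)
            else:
                dcp = 0.0
            mean_cp = base[gene] - dcp
            for rep in range(config.n_replicates):
                cp = mean_cp + (sd * rng.standard_normal() if sd > 0 else 0.0)
                rows.append((gene, cond, rep + 1, cp))
    df = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "Cp"])
    record = {
        "true_folds": dict(true_folds), "eff_target": eff_target, "eff_reference": eff_reference,
        "baseline_cp": base, "seed": config.seed, "cp_sd": sd,
        "target": target, "reference": reference, "control": control,
    }
    return df, record
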