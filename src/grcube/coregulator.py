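"""DNA-free arm of the model: coregulator peptide-array analysis.

On a coregulator peptide microarray (immobilized NR-box peptides probed
with fluorescently detected receptor) no DNA element is present, so the
equilibrium cube collapses to its D = 0 face with four species
{R, LR, RC, LRC}.  The anti-receptor fluorophore sees everything bound to
an immobilized peptide, so the expected signal on a peptide with affinity
Kc is

    signal = gain * Rtot * (f_RC + f_LRC).

Ligand modulation of peptide binding is summarized per peptide by the
modulation index, MI = log2(mean ligand signal / mean vehicle signal):
MI > 0 is ligand-favored binding, MI < 0 ligand-disfavored.  At a
receptor-saturating ligand dose the model predicts sign(MI) = sign(alpha-1)
for that ligand/peptide pair.  Peptides are called favored / unfavored /
unchanged by a per-peptide two-sample t-test on log signals at a declared
alpha level, without multiplicity correction by default (a
Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equilibrium import EquilibriumParams, Milieu, species_fractions

__all__ = [
    "Peptide",
    "PeptidePanel",
    "ModulationProfile",
    "DNA_FREE_SPECIES",
    "dna_free_fractions",
    "binding_signal",
    "simulate_titration",
    "modulation_index",
    "classify_modulation",
    "call_overlap",
    "venn_counts",
]

DNA_FREE_SPECIES = ("R", "LR", "RC", "LRC")


@dataclass(frozen=True)
class Peptide:
    """One NR-box peptide: receptor affinity and per-ligand modulation."""

    peptide_id: str
    Kc: float
    alphas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.Kc > 0 and math.isfinite(self.Kc)):
            raise ValueError(f"Kc must be finite and > 0, got {self.Kc}")
        for lig, a in self.alphas.items():
            if not (a >= 0 and math.isfinite(a)):
                raise ValueError(f"alpha for ligand {lig!r} must be >= 0, got {a}")
        object.__setattr__(self, "alphas", dict(self.alphas))

    def alpha(self, ligand: str) -> float:
        return self.alphas.get(ligand, 1.0)


@dataclass(frozen=True)
class PeptidePanel:
    """Collection of peptides with unique identifiers."""

    peptides: tuple

    def __post_init__(self):
        ids = [p.peptide_id for p in self.peptides]
        if len(set(ids)) != len(ids):
            raise ValueError("peptide identifiers must be unique")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def ids(self) -> list:
        return [p.peptide_id for p in self.peptides]


def dna_free_fractions(params: EquilibriumParams, L: float, C: float) -> dict:
    """Fractions over {R, LR, RC, LRC}: the full model at D = 0."""
    dist = species_fractions(params, Milieu(L=L, C=C, D=0.0))
    return {s: dist[s] for s in DNA_FREE_SPECIES}


def binding_signal(
    params: EquilibriumParams, L: float, C: float, Rtot: float, gain: float
) -> float:
    """Expected array fluorescence: gain * Rtot * (f_RC + f_LRC)."""
    if not gain > 0:
        raise ValueError("gain must be > 0")
    fr = dna_free_fractions(params, L, C)
    return gain * Rtot * (fr["RC"] + fr["LRC"])


def simulate_titration(
    Kc: float,
    peptide_conc: Sequence[float],
    Rtot: float,
    gain: float,
    *,
    Ka: float = 1e8,
    alpha: float = 1.0,
    L: float = 0.0,
) -> pd.DataFrame:
    """Saturation isotherm across a peptide concentration grid.

    In vehicle (L = 0) the saturable component reaches half its plateau at
    C = 1/Kc.
    """
    conc = np.asarray(peptide_conc, dtype=float)
    if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("peptide concentrations must be non-negative and increasing")
    params = EquilibriumParams(Ka=Ka, Kc=Kc, Kd=1.0, alpha=alpha)
    sig = [binding_signal(params, L, c, Rtot, gain) for c in conc]
    return pd.DataFrame({"peptide_conc_M": conc, "signal": sig})


def modulation_index(
    ligand_signals: Sequence[float],
    vehicle_signals: Sequence[float],
    *,
    base: float = 2.0,
    method: str = "ratio-of-means",
) -> float:
    """MI = log_base(mean ligand signal / mean vehicle signal).

    ``method="mean-of-ratios"`` instead averages per-replicate log ratios
    (requires equal replicate counts).
    """
    lig = np.asarray(ligand_signals, dtype=float)
    veh = np.asarray(vehicle_signals, dtype=float)
    if lig.size == 0 or veh.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "ratio-of-means":
        ml, mv = lig.mean(), veh.mean()
        if ml <= 0 or mv <= 0:
            raise ValueError("group means must be positive")
        return float(np.log(ml / mv) / np.log(base))
    if method == "mean-of-ratios":
        if lig.size != veh.size:
            raise ValueError("mean-of-ratios needs paired replicates")
        if np.any(lig <= 0) or np.any(veh <= 0):
            raise ValueError("signals must be positive")
        return float(np.mean(np.log(lig / veh)) / np.log(base))
    raise ValueError("method must be 'ratio-of-means' or 'mean-of-ratios'")


@dataclass(frozen=True)
class ModulationProfile:
    """Per-peptide calls for each ligand plus cross-ligand overlap counts."""

    table: pd.DataFrame  # columns: peptide, ligand, MI, p_value, call
    panel_size: int
    alpha_level: float
    vehicle: str

    def calls(self, ligand: str) -> pd.Series:
        t = self.table[self.table["ligand"] == ligand]
        return t.set_index("peptide")["call"]

    def counts(self, ligand: str) -> dict:
        c = self.calls(ligand).value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("favored", "unfavored", "unchanged", "unclassifiable")}


def classify_modulation(
    data: pd.DataFrame,
    *,
    vehicle: str = "vehicle",
    alpha_level: float = 0.05,
    mi_base: float = 2.0,
    bh_correct: bool = False,
) -> ModulationProfile:
    """Call each peptide favored/unfavored/unchanged per ligand.

    ``data`` is long format with columns peptide, condition, replicate,
    signal.  Per peptide and ligand: MI from the ratio of group means and an
    unpaired equal-variance t-test on log signals against vehicle.  Peptides
    with fewer than two replicates in either group are marked
    unclassifiable and excluded from overlap counts.  ``bh_correct`` applies
    Benjamini-Hochberg across the panel (off by default).
    """
    for col in ("peptide", "condition", "replicate", "signal"):
        if col not in data.columns:
            raise ValueError(f"array dataset must have a {col!r} column")
    if not (data["signal"] >= 0).all() or not np.isfinite(data["signal"]).all():
        raise ValueError("signals must be finite and >= 0")
    conditions = [c for c in data["condition"].unique() if c != vehicle]
    if vehicle not in set(data["condition"]):
        raise ValueError("no vehicle condition in dataset")

    rows = []
    for ligand in conditions:
        sub = data[data["condition"].isin([ligand, vehicle])]
        for peptide, grp in sub.groupby("peptide"):
            lig = grp.loc[grp["condition"] == ligand, "signal"].to_numpy(dtype=float)
            veh = grp.loc[grp["condition"] == vehicle, "signal"].to_numpy(dtype=float)
            if lig.size < 2 or veh.size < 2:
                rows.append((peptide, ligand, np.nan, np.nan, "unclassifiable"))
                continue
            mi = modulation_index(lig, veh, base=mi_base)
            if np.all(lig == lig[0]) and np.all(veh == veh[0]) and lig[0] == veh[0]:
                p = 1.0  # identical constant groups: no evidence of change
            else:
                _, p = stats.ttest_ind(np.log(lig), np.log(veh), equal_var=True)
                p = float(p) if np.isfinite(p) else 1.0
            rows.append((peptide, ligand, mi, p, None))

    table = pd.DataFrame(rows, columns=["peptide", "ligand", "MI", "p_value", "call"])
    if bh_correct:
        for ligand in conditions:
            m = (table["ligand"] == ligand) & table["p_value"].notna()
            p = table.loc[m, "p_value"].to_numpy()
            order = np.argsort(p)
            q = np.empty_like(p)
            n = p.size
            prev = 1.0
            for rank in range(n - 1, -1, -1):
                i = order[rank]
                prev = min(prev, p[i] * n / (rank + 1))
                q[i] = prev
            table.loc[m, "p_value"] = q

    def call(row):
        if row["call"] == "unclassifiable":
            return "unclassifiable"
        if row["p_value"] < alpha_level and row["MI"] > 0:
            return "favored"
        if row["p_value"] < alpha_level and row["MI"] < 0:
            return "unfavored"
        return "unchanged"

    table["call"] = table.apply(call, axis=1)
    panel_size = int(data["peptide"].nunique())
    return ModulationProfile(table=table, panel_size=panel_size, alpha_level=alpha_level, vehicle=vehicle)


def call_overlap(
    profile: ModulationProfile, ligand_a: str, call_a: str, ligand_b: str, call_b: str
) -> int:
    """Number of peptides with ``call_a`` under ligand A and ``call_b`` under B."""
    ca, cb = profile.calls(ligand_a), profile.calls(ligand_b)
    a = set(ca.index[ca == call_a])
    b = set(cb.index[cb == call_b])
    return len(a & b)


def venn_counts(profile: ModulationProfile, call: str, ligands: "Sequence[str] | None" = None) -> dict:
    """Region counts of the Venn diagram of peptide sets with one call.

    Keys are frozensets of ligand names (the exclusive region each peptide
    set occupies); also returns per-ligand totals under ``("total", ligand)``.
    """
    if ligands is None:
        ligands = sorted(profile.table["ligand"].unique())
    sets = {}
    for l in ligands:
        c = profile.calls(l)
        sets[l] = set(c.index[c == call])
    out = {("total", l): len(sets[l]) for l in ligands}
    for r in range(1, len(ligands) + 1):
        for combo in combinations(ligands, r):
            inside = set.intersection(*(sets[l] for l in combo)) if combo else set()
            outside = set.union(*(sets[l] for l in ligands if l not in combo), set())
            out[frozenset(combo)] = len(inside - outside)
    return out
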