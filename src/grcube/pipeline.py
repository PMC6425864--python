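"""End-to-end scenarios: synthesize -> analyze -> summarize, with manifests.

A scenario is a JSON document that fully specifies a run (model parameters,
design, synthesis config, analysis options, seed).  ``run_scenario``
executes the stage chain for the scenario kind, writes tidy CSV outputs, a
JSON summary and a manifest recording the seed, package version and SHA-256
hash of every produced file, so re-running a scenario with its recorded
seed reproduces the manifest hashes bit for bit.

Shipped scenarios (``grcube/scenarios/*.json``) cover the model's
demonstration patterns: the parameter-sensitivity scan in which delta is
the only "both"-mover, receptor knockdown (Rmax proportional, EC50 fixed),
coregulator knockdown with delta != 1 (both move), ligand competition,
array classification, and the qPCR round trip.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import coregulator, dose_response, fitting, qpcr, synth
from .equilibrium import EquilibriumParams, Milieu, ResponseSpec

__all__ = [
    "ScenarioError",
    "load_scenario",
    "shipped_scenario_path",
    "run_scenario",
    "validate_inputs",
    "SCHEMAS",
]

log = logging.getLogger("grcube")

SCENARIO_KINDS = (
    "sensitivity-scan",
    "receptor-knockdown",
    "coregulator-knockdown",
    "competition",
    "marconi",
    "qpcr",
)

_REQUIRED_KEYS = ("schema_version", "name", "kind", "seed")


class ScenarioError(RuntimeError):
    """A stage of a scenario failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def load_scenario(path) -> dict:
    cfg = json.loads(Path(path).read_text())
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"scenario is missing required keys: {missing}")
    if cfg["kind"] not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {cfg['kind']!r}; choose from {SCENARIO_KINDS}")
    return cfg


def shipped_scenario_path(name: str) -> Path:
    """Path to a scenario JSON shipped with the package."""
    p = resources.files("grcube").joinpath("scenarios", f"{name}.json")
    return Path(str(p))


def _model_from(cfg: dict):
    params = EquilibriumParams.from_dict(cfg["params"])
    milieu = Milieu(**cfg["milieu"])
    spec = ResponseSpec.from_dict(cfg.get("response", {}))
    return params, milieu, spec


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _summaries_frame(items) -> pd.DataFrame:
    rows = []
    for label, s in items:
        rows.append({"scenario": label, "pEC50": s.pEC50, "EC50_M": s.EC50, "Rmax": s.Rmax, "basal": s.basal})
    return pd.DataFrame(rows)


def _run_sensitivity(cfg: dict, outdir: Path) -> dict:
    params, milieu, spec = _model_from(cfg)
    opts = cfg.get("options", {})
    reports = []
    for p in opts.get("parameters", ["alpha", "beta", "gamma", "delta"]):
        reports.append(
            dose_response.classify_parameter_sensitivity(
                params, milieu, spec, p,
                fold_range=opts.get("fold_range", 100.0),
                threshold=opts.get("threshold", 1.25),
            )
        )
    df = pd.DataFrame([r.to_dict() for r in reports])
    _write_csv(df, outdir / "sensitivity.csv")
    return {"labels": {r.parameter: r.label for r in reports},
            "ec50_ratios": {r.parameter: r.ec50_ratio for r in reports},
            "rmax_ratios": {r.parameter: r.rmax_ratio for r in reports}}


def _run_receptor_knockdown(cfg: dict, outdir: Path) -> dict:
    params, milieu, spec = _model_from(cfg)
    opts = cfg.get("options", {})
    scales = opts.get("scales", [1.0, 0.6, 0.15])
    preds = dose_response.predict_receptor_knockdown(params, milieu, spec, scales)
    _write_csv(pd.concat([p.curve for p in preds]), outdir / "curves.csv")
    summ = _summaries_frame([(f"scale-{p.scale:g}", p.summary) for p in preds])
    _write_csv(summ, outdir / "summaries.csv")
    base = preds[0].summary
    return {
        "scales": scales,
        "pEC50": [p.summary.pEC50 for p in preds],
        "rmax_ratio_vs_scale": [p.summary.Rmax / (base.Rmax * p.scale / preds[0].scale) for p in preds],
    }


def _run_coregulator_knockdown(cfg: dict, outdir: Path) -> dict:
    params, milieu, spec = _model_from(cfg)
    opts = cfg.get("options", {})
    scales = opts.get("scales", [1.0, 0.1])
    out = {}
    frames = []
    for tag, p in (("delta-scenario", params), ("independence-control", params.replace(delta=1.0, alpha=1.0, beta=1.0, gamma=1.0))):
        preds = dose_response.predict_coregulator_knockdown(p, milieu, spec, scales)
        frames.append(_summaries_frame([(f"{tag}/scale-{q.scale:g}", q.summary) for q in preds]))
        ec = [q.summary.EC50 for q in preds]
        rm = [q.summary.Rmax for q in preds]
        out[tag] = {"ec50_ratio": max(ec) / min(ec), "rmax_ratio": max(rm) / min(rm)}
    _write_csv(pd.concat(frames), outdir / "summaries.csv")
    return out


def _run_competition(cfg: dict, outdir: Path) -> dict:
    opts = cfg.get("options", {})
    df, record = synth.gen_competition(
        cfg["shared"], cfg["agonist"], cfg["modulator"], opts.get("modulator_dose_M", 1e-7),
        synth.SyntheticConfig(seed=cfg["seed"], dose_response_cv=opts.get("cv", 0.1)),
        milieu=cfg.get("milieu"), efficacies=opts.get("efficacies"),
        epsilon=opts.get("epsilon", 1.0),
    )
    _write_csv(df, outdir / "competition.csv")
    (outdir / "competition.truth.json").write_text(json.dumps(record, indent=1))
    from .equilibrium import LigandParams

    pred = dose_response.predict_competition(
        EquilibriumParams.from_dict({"Ka": 1.0, **cfg["shared"]}),
        LigandParams(**cfg["agonist"]), LigandParams(**cfg["modulator"]),
        Milieu(**cfg["milieu"]),
        efficacies=opts.get("efficacies"), epsilon=opts.get("epsilon", 1.0),
        modulator_dose=opts.get("modulator_dose_M", 1e-7),
    )
    return {"pEC50": pred.summary.pEC50, "Rmax": pred.summary.Rmax, "basal": pred.summary.basal}


def _run_marconi(cfg: dict, outdir: Path) -> dict:
    opts = cfg.get("options", {})
    panel = synth.default_panel(seed=cfg["seed"], n_peptides=opts.get("n_peptides", 53))
    ligands = opts.get("ligands", ["DEX", "RU486", "CYP"])
    df, record = synth.gen_marconi(
        panel, ligands, synth.SyntheticConfig(seed=cfg["seed"], array_cv=opts.get("cv", 0.1))
    )
    _write_csv(df, outdir / "array.csv")
    (outdir / "array.truth.json").write_text(json.dumps(record, indent=1))
    profile = coregulator.classify_modulation(df, alpha_level=opts.get("alpha_level", 0.05))
    _write_csv(profile.table, outdir / "modulation.csv")
    counts = {lig: profile.counts(lig) for lig in ligands}
    overlap = {
        "favored_DEX_unfavored_CYP": coregulator.call_overlap(profile, "DEX", "favored", "CYP", "unfavored")
        if {"DEX", "CYP"} <= set(ligands) else None,
    }
    (outdir / "overlaps.json").write_text(json.dumps({"counts": counts, "overlap": overlap}, indent=1))
    return {"counts": counts, "overlap": overlap}


def _run_qpcr(cfg: dict, outdir: Path) -> dict:
    opts = cfg.get("options", {})
    folds = opts.get("true_folds", {"treated": 4.0})
    plate, record = synth.gen_qpcr_plate(
        folds,
        synth.SyntheticConfig(seed=cfg["seed"], qpcr_cp_sd=opts.get("cp_sd", 0.15)),
        eff_target=opts.get("eff_target", 2.0), eff_reference=opts.get("eff_reference", 2.0),
    )
    _write_csv(plate, outdir / "plate.csv")
    (outdir / "plate.truth.json").write_text(json.dumps(record, indent=1))
    results = qpcr.plate_to_folds(
        plate, "target", "reference",
        opts.get("eff_target", 2.0), opts.get("eff_reference", 2.0),
    )
    _write_csv(pd.DataFrame([r.to_dict() for r in results]), outdir / "folds.csv")
    return {"folds": {r.condition: r.fold for r in results}, "true_folds": folds}


_RUNNERS = {
    "sensitivity-scan": _run_sensitivity,
    "receptor-knockdown": _run_receptor_knockdown,
    "coregulator-knockdown": _run_coregulator_knockdown,
    "competition": _run_competition,
    "marconi": _run_marconi,
    "qpcr": _run_qpcr,
}


def run_scenario(config, outdir) -> dict:
    """Run a scenario (dict or path to JSON); returns the manifest."""
    cfg = load_scenario(config) if not isinstance(config, dict) else config
    missing = [k for k in _REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ValueError(f"scenario is missing required keys: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("running scenario %s (kind=%s, seed=%s)", cfg["name"], cfg["kind"], cfg["seed"])
    try:
        summary = _RUNNERS[cfg["kind"]](cfg, outdir)
    except Exception as err:
        partial = {"scenario": cfg["name"], "kind": cfg["kind"], "seed": cfg["seed"],
                   "status": "failed", "stage": cfg["kind"], "error": str(err)}
        (outdir / "manifest.json").write_text(json.dumps(partial, indent=1))
        raise ScenarioError(cfg["kind"], str(err)) from err
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    try:
        version = metadata.version("grcube")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    files = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "scenario": cfg["name"],
        "kind": cfg["kind"],
        "seed": cfg["seed"],
        "status": "ok",
        "package_version": version,
        "files": {p.name: _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# input validation


def _validate_dose_response(df: pd.DataFrame) -> list:
    problems = []
    for col in ("dose_M", "response"):
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        return problems
    bad = df.index[df["dose_M"] < 0]
    problems += [f"row {i}: negative dose {df.loc[i, 'dose_M']}" for i in bad]
    nonfinite = df.index[~np.isfinite(df["response"])]
    problems += [f"row {i}: non-finite response" for i in nonfinite]
    return problems


def _validate_marconi(df: pd.DataFrame) -> list:
    problems = []
    for col in ("peptide", "condition", "replicate", "signal"):
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        return problems
    if "vehicle" not in set(df["condition"]):
        problems.append("no vehicle condition")
    bad = df.index[(df["signal"] < 0) | ~np.isfinite(df["signal"])]
    problems += [f"row {i}: invalid signal" for i in bad]
    return problems


def _validate_qpcr_plate(df: pd.DataFrame) -> list:
    problems = []
    for col in ("gene", "condition", "replicate", "Cp"):
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if problems:
        return problems
    bad = df.index[(df["Cp"] <= 0) | (df["Cp"] >= 45) | ~np.isfinite(df["Cp"])]
    problems += [f"row {i}: Cp out of (0, 45)" for i in bad]
    return problems


def _validate_standard_curve(df: pd.DataFrame) -> list:
    problems = []
    for col in ("dilution_log10", "Cp"):
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    if not problems and df["dilution_log10"].nunique() < 3:
        problems.append("fewer than 3 dilution levels")
    return problems


SCHEMAS = {
    "dose_response": _validate_dose_response,
    "marconi": _validate_marconi,
    "qpcr_plate": _validate_qpcr_plate,
    "standard_curve": _validate_standard_curve,
}


def validate_inputs(path, schema: str) -> tuple:
    """Validate a CSV/JSON input file against a named schema.

    Returns ``(ok, diagnostics)`` where diagnostics lists offending rows.
    """
    if schema == "scenario":
        try:
            load_scenario(path)
            return True, []
        except (ValueError, json.JSONDecodeError) as err:
            return False, [str(err)]
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)} or 'scenario'")
    df = pd.read_csv(path)
    problems = SCHEMAS[schema](df)
    return (len(problems) == 0), problems
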