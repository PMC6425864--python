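"""Grid-search the committed demonstration regimes and write scenario JSONs.

The model does not come with canonical parameter values for its two
demonstration patterns, so they are discovered here rather than hand-picked:

1. ``sensitivity-scan``: a baseline in which 100-fold scans of alpha, beta
   and gamma each move only one dose-response summary (EC50 or Rmax) at
   threshold ratio 1.25, while the same scan of delta moves both.  The
   search maximizes the worst-case margin to the 1.25 threshold over a
   log grid of occupancy products Kc*C = Kd*D and baseline beta.

2. ``coregulator-knockdown``: a delta != 1 regime in which reducing the
   coregulator concentration 10-fold moves both EC50 and Rmax by >= 1.25x,
   searched over delta and the occupancy products, next to the
   alpha=beta=gamma=delta=1 control in which only Rmax moves.

Run from the repository root:

    python scripts/find_baseline.py [--out src/grcube/scenarios]
"""

from __future__ import annotations

import argparse
import json
import math
from pathlib import Path

import numpy as np

from grcube.dose_response import classify_parameter_sensitivity, summarize_curve
from grcube.equilibrium import EquilibriumParams, Milieu, ResponseSpec

THRESHOLD = 1.25
FOLD = 100.0


def margin(ratio: float, should_move: bool) -> float:
    """Log-scale distance to the threshold, positive when on the right side."""
    return (math.log(ratio) - math.log(THRESHOLD)) * (1 if should_move else -1)


def score_sensitivity(c: float, beta: float, Ka: float = 1e8) -> tuple:
    """Worst-case margin of the Fig-2 pattern at Kc*C = Kd*D = c."""
    params = EquilibriumParams(Ka=Ka, Kc=1e9, Kd=1e9, beta=beta)
    milieu = Milieu(L=0.0, C=c / 1e9, D=c / 1e9, Rtot=1.0)
    spec = ResponseSpec()
    margins, labels = [], {}
    for p in ("alpha", "beta", "gamma", "delta"):
        r = classify_parameter_sensitivity(params, milieu, spec, p, FOLD, threshold=THRESHOLD)
        labels[p] = r.label
        moved_e, moved_r = r.label in ("both", "EC50-only"), r.label in ("both", "Rmax-only")
        if p == "delta":
            margins += [margin(r.ec50_ratio, True), margin(r.rmax_ratio, True)]
        else:
            # single mover: exactly one ratio above threshold, the other below
            hi, lo = max(r.ec50_ratio, r.rmax_ratio), min(r.ec50_ratio, r.rmax_ratio)
            margins += [margin(hi, True), margin(lo, False)]
    return min(margins), labels


def search_sensitivity() -> dict:
    best = None
    for c in np.geomspace(1, 1e4, 17):
        for beta in np.geomspace(1e-3, 10, 17):
            try:
                m, labels = score_sensitivity(float(c), float(beta))
            except Exception:
                continue
            ok = labels["delta"] == "both" and all(
                labels[p] in ("EC50-only", "Rmax-only") for p in ("alpha", "beta", "gamma")
            )
            if ok and (best is None or m > best[0]):
                best = (m, float(c), float(beta), labels)
    if best is None:
        raise SystemExit("no sensitivity baseline found on the grid")
    m, c, beta, labels = best
    print(f"sensitivity baseline: Kc*C = Kd*D = {c:g}, beta = {beta:g}, "
          f"margin {m:.3f}, labels {labels}")
    return {
        "schema_version": 1,
        "name": "sensitivity-scan",
        "kind": "sensitivity-scan",
        "seed": 1,
        "params": {"Ka": 1e8, "Kc": 1e9, "Kd": 1e9, "alpha": 1.0, "beta": beta, "gamma": 1.0, "delta": 1.0},
        "milieu": {"L": 0.0, "C": c / 1e9, "D": c / 1e9, "Rtot": 1.0},
        "response": {"coefficients": {"LRCD": 1.0}, "epsilon": 34.0},
        "options": {"fold_range": FOLD, "threshold": THRESHOLD,
                    "parameters": ["alpha", "beta", "gamma", "delta"]},
    }


def score_knockdown(delta: float, c: float, scale: float = 0.1) -> tuple:
    params = EquilibriumParams(Ka=1e9, Kc=1e9, Kd=1e9, delta=delta)
    milieu = Milieu(L=0.0, C=c / 1e9, D=c / 1e9, Rtot=1.0)
    spec = ResponseSpec(epsilon=6.7)
    s1 = summarize_curve(params, milieu, spec)
    s2 = summarize_curve(params, milieu.replace(C=milieu.C * scale), spec)
    er = max(s1.EC50, s2.EC50) / min(s1.EC50, s2.EC50)
    rr = max(s1.Rmax, s2.Rmax) / min(s1.Rmax, s2.Rmax)
    return min(margin(er, True), margin(rr, True)), er, rr


def search_knockdown() -> dict:
    best = None
    for delta in np.geomspace(2, 100, 12):
        for c in np.geomspace(0.03, 30, 13):
            m, er, rr = score_knockdown(float(delta), float(c))
            if best is None or m > best[0]:
                best = (m, float(delta), float(c), er, rr)
    m, delta, c, er, rr = best
    if m <= 0:
        raise SystemExit("no coregulator-knockdown regime found on the grid")
    print(f"coregulator knockdown: delta = {delta:g}, Kc*C = Kd*D = {c:g}, "
          f"EC50 ratio {er:.3f}, Rmax ratio {rr:.3f}")
    return {
        "schema_version": 1,
        "name": "coregulator-knockdown",
        "kind": "coregulator-knockdown",
        "seed": 1,
        "params": {"Ka": 1e9, "Kc": 1e9, "Kd": 1e9, "alpha": 1.0, "beta": 1.0, "gamma": 1.0, "delta": delta},
        "milieu": {"L": 0.0, "C": c / 1e9, "D": c / 1e9, "Rtot": 1.0},
        "response": {"coefficients": {"LRCD": 1.0}, "epsilon": 6.7},
        "options": {"scales": [1.0, 0.1], "threshold": THRESHOLD},
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="src/grcube/scenarios", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for cfg in (search_sensitivity(), search_knockdown()):
        path = args.out / f"{cfg['name']}.json"
        path.write_text(json.dumps(cfg, indent=1) + "\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
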