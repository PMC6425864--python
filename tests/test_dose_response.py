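"""Tests for curve simulation, summaries, sensitivity and predictions."""

import numpy as np
import pytest

from grcube.dose_response import (
    DoseGrid,
    NoResponseError,
    basal_analytic,
    classify_parameter_sensitivity,
    ec50_analytic,
    log_dose_grid,
    predict_competition,
    predict_coregulator_knockdown,
    predict_receptor_knockdown,
    rmax_analytic,
    simulate_curve,
    summarize_curve,
)
from grcube.equilibrium import EquilibriumParams, LigandParams, Milieu, ResponseSpec
from conftest import random_milieu, random_params


class TestSimulateCurve:
    def test_independence_closed_form(self, unit_params, default_spec):
        milieu = Milieu(L=0.0, C=3e-10, D=7e-10, Rtot=2.0)
        grid = log_dose_grid(1e-12, 1e-6, 10)
        curve = simulate_curve(unit_params, milieu, default_spec, grid)
        kc = unit_params.Kc * milieu.C
        kd = unit_params.Kd * milieu.D
        for dose, resp in zip(curve["dose_M"], curve["response"]):
            kl = unit_params.Ka * dose
            expect = milieu.Rtot * (kc / (1 + kc)) * (kd / (1 + kd)) * kl / (1 + kl)
            assert resp == pytest.approx(expect, rel=1e-12)

    def test_vanishing_dose_approaches_basal(self, unit_params, default_spec):
        milieu = Milieu(L=0.0, C=1e-9, D=1e-9)
        curve = simulate_curve(unit_params, milieu, default_spec, DoseGrid((1e-18,)))
        assert curve["response"].iloc[0] == pytest.approx(
            basal_analytic(unit_params, milieu, default_spec), abs=1e-9
        )

    def test_epsilon_doubles_every_point(self, unit_params):
        milieu = Milieu(L=0.0, C=1e-9, D=1e-9)
        grid = log_dose_grid()
        c1 = simulate_curve(unit_params, milieu, ResponseSpec(epsilon=1.0), grid)
        c2 = simulate_curve(unit_params, milieu, ResponseSpec(epsilon=2.0), grid)
        assert np.allclose(c2["response"], 2 * c1["response"], rtol=1e-15)

    def test_dose_grid_validation(self):
        with pytest.raises(ValueError):
            DoseGrid((1e-9, 1e-9))
        with pytest.raises(ValueError):
            DoseGrid((0.0, 1e-9))


class TestSummarizeCurve:
    def test_ec50_is_reciprocal_ka_at_unit_cooperativities(self, unit_params, default_spec):
        milieu = Milieu(L=0.0, C=5e-10, D=2e-9)
        s = summarize_curve(unit_params, milieu, default_spec)
        assert s.EC50 == pytest.approx(1.0 / unit_params.Ka, rel=1e-6)
        assert s.pEC50 == pytest.approx(-np.log10(s.EC50), abs=1e-12)

    def test_bisection_matches_ratio_of_denominators(self, default_spec):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p, m = random_params(rng), random_milieu(rng).replace(L=0.0)
            s = summarize_curve(p, m, default_spec)
            assert s.EC50 == pytest.approx(ec50_analytic(p, m, default_spec), rel=1e-6)

    def test_rtot_scaling_moves_rmax_not_ec50(self, unit_params, default_spec):
        m = Milieu(L=0.0, C=1e-9, D=1e-9, Rtot=1.0)
        s1 = summarize_curve(unit_params, m, default_spec)
        s2 = summarize_curve(unit_params, m.replace(Rtot=3.0), default_spec)
        assert s2.EC50 == pytest.approx(s1.EC50, rel=1e-9)
        assert s2.Rmax == pytest.approx(3 * s1.Rmax, rel=1e-12)

    def test_flat_curve_raises(self, unit_params):
        # zero coregulator: LRCD can never form, response identically 0
        m = Milieu(L=0.0, C=0.0, D=1e-9)
        with pytest.raises(NoResponseError):
            summarize_curve(unit_params, m, ResponseSpec())

    def test_basal_nonzero_with_rcd_coefficient(self, unit_params):
        m = Milieu(L=0.0, C=1e-9, D=1e-9)
        spec = ResponseSpec(coefficients={"LRCD": 1.0, "RCD": 0.3})
        s = summarize_curve(unit_params, m, spec)
        assert s.basal == pytest.approx(basal_analytic(unit_params, m, spec), rel=1e-12)
        assert 0 < s.basal < s.Rmax
        # the ratio-of-denominators EC50 is numerator-free: still d0/d1
        assert s.EC50 == pytest.approx(ec50_analytic(unit_params, m, spec), rel=1e-6)


class TestSensitivity:
    BASE = EquilibriumParams(Ka=1e8, Kc=1e9, Kd=1e9)
    LOW_OCC = Milieu(L=0.0, C=1e-11, D=1e-11)  # Kc*C = Kd*D = 0.01

    def test_degenerate_fold_range_is_neither(self, default_spec):
        r = classify_parameter_sensitivity(self.BASE, self.LOW_OCC, default_spec, "alpha", 1.0)
        assert r.label == "neither"
        assert r.ec50_ratio == pytest.approx(1.0) and r.rmax_ratio == pytest.approx(1.0)

    def test_alpha_is_rmax_only_at_low_occupancy(self, default_spec):
        r = classify_parameter_sensitivity(self.BASE, self.LOW_OCC, default_spec, "alpha", 100.0)
        assert r.label == "Rmax-only"
        assert r.rmax_ratio >= 1.25 and r.ec50_ratio < 1.25

    def test_delta_is_both_at_committed_baseline(self, default_spec):
        # the committed grid-searched regime (see scenario file)
        import json
        from grcube.pipeline import shipped_scenario_path

        cfg = json.loads(shipped_scenario_path("sensitivity-scan").read_text())
        p = EquilibriumParams.from_dict(cfg["params"])
        m = Milieu(**cfg["milieu"])
        spec = ResponseSpec.from_dict(cfg["response"])
        labels = {
            name: classify_parameter_sensitivity(p, m, spec, name, 100.0).label
            for name in ("alpha", "beta", "gamma", "delta")
        }
        assert labels["delta"] == "both"
        assert labels["alpha"] in ("EC50-only", "Rmax-only")
        assert labels["beta"] in ("EC50-only", "Rmax-only")
        assert labels["gamma"] in ("EC50-only", "Rmax-only")

    def test_scan_direction_invariance(self, default_spec):
        # scanning x over [1/f, f] visits the same models as scanning 1/x
        r1 = classify_parameter_sensitivity(self.BASE, self.LOW_OCC, default_spec, "alpha", 100.0)
        vals = np.array(r1.scan_values)
        assert np.allclose(sorted(vals), sorted(self.BASE.alpha / (vals / self.BASE.alpha)), rtol=1e-12)

    def test_unknown_parameter_rejected(self, default_spec):
        with pytest.raises(ValueError):
            classify_parameter_sensitivity(self.BASE, self.LOW_OCC, default_spec, "zeta", 10.0)


class TestKnockdownPredictions:
    PARAMS = EquilibriumParams(Ka=1e9, Kc=1e9, Kd=1e9)
    MILIEU = Milieu(L=0.0, C=1e-9, D=1e-9, Rtot=1.0)

    def test_receptor_knockdown_scales_rmax_keeps_ec50(self, default_spec):
        preds = predict_receptor_knockdown(self.PARAMS, self.MILIEU, default_spec, [1.0, 0.5, 0.2])
        base = preds[0].summary
        for p in preds:
            assert p.summary.EC50 == pytest.approx(base.EC50, rel=1e-9)
            assert p.summary.Rmax == pytest.approx(p.scale * base.Rmax, rel=1e-9)
        rmaxes = [p.summary.Rmax for p in preds]
        assert rmaxes == sorted(rmaxes, reverse=True)

    def test_scale_one_is_baseline(self, default_spec):
        preds = predict_receptor_knockdown(self.PARAMS, self.MILIEU, default_spec, [1.0])
        base = summarize_curve(self.PARAMS, self.MILIEU, default_spec)
        assert preds[0].summary.Rmax == pytest.approx(base.Rmax, rel=1e-12)

    def test_invalid_scale_rejected(self, default_spec):
        with pytest.raises(ValueError):
            predict_receptor_knockdown(self.PARAMS, self.MILIEU, default_spec, [1.5])

    def test_coregulator_knockdown_independence_control(self, default_spec):
        preds = predict_coregulator_knockdown(self.PARAMS, self.MILIEU, default_spec, [1.0, 0.3])
        # at unit cooperativities EC50 = 1/Ka regardless of C; Rmax falls
        for p in preds:
            assert p.summary.EC50 == pytest.approx(1.0 / self.PARAMS.Ka, rel=1e-6)
        assert preds[1].summary.Rmax < preds[0].summary.Rmax

    def test_coregulator_knockdown_delta_regime_moves_both(self, default_spec):
        import json
        from grcube.pipeline import shipped_scenario_path

        cfg = json.loads(shipped_scenario_path("coregulator-knockdown").read_text())
        p = EquilibriumParams.from_dict(cfg["params"])
        m = Milieu(**cfg["milieu"])
        spec = ResponseSpec.from_dict(cfg["response"])
        preds = predict_coregulator_knockdown(p, m, spec, cfg["options"]["scales"])
        ec = [q.summary.EC50 for q in preds]
        rm = [q.summary.Rmax for q in preds]
        assert max(ec) / min(ec) >= 1.25
        assert max(rm) / min(rm) >= 1.25


class TestCompetition:
    SHARED = EquilibriumParams(Ka=1.0, Kc=1e9, Kd=1e9)
    AG = LigandParams(name="AG", Ka=1e9)
    MILIEU = Milieu(L=0.0, C=1e-9, D=1e-9, Rtot=1.0)

    def test_zero_modulator_dose_recovers_agonist_curve(self, default_spec):
        mod = LigandParams(name="MOD", Ka=1e8)
        pred = predict_competition(
            self.SHARED, self.AG, mod, self.MILIEU, modulator_dose=0.0
        )
        single = EquilibriumParams(Ka=self.AG.Ka, Kc=self.SHARED.Kc, Kd=self.SHARED.Kd)
        s = summarize_curve(single, self.MILIEU, default_spec)
        assert pred.summary.EC50 == pytest.approx(s.EC50, rel=1e-5)
        assert pred.summary.Rmax == pytest.approx(s.Rmax, rel=1e-9)

    def test_identical_modulator_keeps_plateau_and_left_shifts(self):
        mod = LigandParams(name="MOD", Ka=1e9)
        alone = predict_competition(self.SHARED, self.AG, mod, self.MILIEU, modulator_dose=0.0,
                                    efficacies={"AG": 1.0, "MOD": 1.0})
        boosted = predict_competition(self.SHARED, self.AG, mod, self.MILIEU, modulator_dose=1e-8,
                                      efficacies={"AG": 1.0, "MOD": 1.0})
        assert boosted.summary.Rmax == pytest.approx(alone.summary.Rmax, rel=1e-9)
        # an equally efficacious partner raises the curve everywhere below plateau
        assert np.all(boosted.curve["response"].to_numpy() >= alone.curve["response"].to_numpy() - 1e-15)

    def test_saturating_silent_modulator_suppresses_response(self):
        mod = LigandParams(name="MOD", Ka=1e10)
        alone = predict_competition(self.SHARED, self.AG, mod, self.MILIEU, modulator_dose=0.0)
        blocked = predict_competition(self.SHARED, self.AG, mod, self.MILIEU, modulator_dose=1e-5)
        mid_dose = 1.0 / self.AG.Ka
        r_alone = np.interp(mid_dose, alone.curve["dose_M"], alone.curve["response"])
        r_block = np.interp(mid_dose, blocked.curve["dose_M"], blocked.curve["response"])
        assert r_block < 0.05 * r_alone
        # a pure competitor does not change the asymptotic plateau
        assert blocked.summary.Rmax == pytest.approx(alone.summary.Rmax, rel=1e-9)
        # but right-shifts the curve
        assert blocked.summary.EC50 > 10 * alone.summary.EC50
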