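"""Unit and property tests for the eight-species equilibrium cube."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grcube.equilibrium import (
    SPECIES,
    ConvergenceError,
    EquilibriumParams,
    LigandParams,
    Milieu,
    ResponseSpec,
    WeightOverflowError,
    multi_ligand_fractions,
    solve_conserved,
    species_fractions,
    statistical_weights,
    transcriptional_response,
)
from conftest import random_milieu, random_params


class TestStatisticalWeights:
    def test_identity_substitution_gives_unit_weights(self, unit_params, unit_milieu):
        w = statistical_weights(unit_params, unit_milieu)
        assert np.allclose(w, 1.0, rtol=1e-12)

    def test_zero_ligand_zeroes_ligand_species_exactly(self, unit_params, unit_milieu):
        w = statistical_weights(unit_params, unit_milieu.replace(L=0.0))
        for s in ("LR", "LRC", "LRD", "LRCD"):
            assert w[SPECIES.index(s)] == 0.0
        for s in ("R", "RC", "RD", "RCD"):
            assert w[SPECIES.index(s)] > 0.0

    def test_delta_only_scales_fully_bound_species(self, unit_params, unit_milieu):
        w = statistical_weights(unit_params.replace(delta=2.0), unit_milieu)
        assert w[SPECIES.index("LRCD")] == pytest.approx(2.0, rel=1e-12)
        assert np.allclose(np.delete(w, SPECIES.index("LRCD")), 1.0, rtol=1e-12)

    def test_overflow_names_the_species(self):
        p = EquilibriumParams(Ka=1e300, Kc=1e300, Kd=1e300)
        with pytest.raises(WeightOverflowError, match="LR"):
            statistical_weights(p, Milieu(L=1e10, C=1e10, D=1e10))
        # only the triple product overflows here, so LRCD is the species named
        p2 = EquilibriumParams(Ka=1e150, Kc=1e150, Kd=1e150)
        with pytest.raises(WeightOverflowError, match="LRCD"):
            statistical_weights(p2, Milieu(L=1.0, C=1.0, D=1.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumParams(Ka=-1.0, Kc=1.0, Kd=1.0)
        with pytest.raises(ValueError):
            EquilibriumParams(Ka=1.0, Kc=1.0, Kd=1.0, alpha=-0.5)
        with pytest.raises(ValueError):
            Milieu(L=-1e-9, C=0, D=0)


class TestSpeciesFractions:
    def test_uniform_weights_give_one_eighth(self, unit_params, unit_milieu):
        f = species_fractions(unit_params, unit_milieu).as_array()
        assert np.allclose(f, 1.0 / 8.0, rtol=1e-12)

    def test_delta_two_gives_two_ninths_lrcd(self, unit_params, unit_milieu):
        dist = species_fractions(unit_params.replace(delta=2.0), unit_milieu)
        assert dist["LRCD"] == pytest.approx(2.0 / 9.0, rel=1e-12)

    def test_independence_factorization(self):
        # at alpha=beta=gamma=delta=1 the LRCD fraction is a product of
        # three independent single-site occupancies
        rng = np.random.default_rng(42)
        for _ in range(50):
            Ka, Kc, Kd = 10.0 ** rng.uniform(6, 10, 3)
            L, C, D = 10.0 ** rng.uniform(-12, -5, 3)
            dist = species_fractions(EquilibriumParams(Ka=Ka, Kc=Kc, Kd=Kd), Milieu(L=L, C=C, D=D))
            expect = (Ka * L / (1 + Ka * L)) * (Kc * C / (1 + Kc * C)) * (Kd * D / (1 + Kd * D))
            assert dist["LRCD"] == pytest.approx(expect, abs=1e-12, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        f = species_fractions(random_params(rng), random_milieu(rng)).as_array()
        assert np.all(f >= 0.0) and np.all(f <= 1.0)
        assert abs(f.sum() - 1.0) < 1e-12

    def test_log_space_path_handles_huge_weights(self):
        p = EquilibriumParams(Ka=1e200, Kc=1e200, Kd=1e10)
        f = species_fractions(p, Milieu(L=1.0, C=1.0, D=0.0))
        assert abs(f.as_array().sum() - 1.0) < 1e-12
        assert f["RD"] == 0.0 and f["LRCD"] == 0.0  # D absent
        assert f["LRC"] == pytest.approx(1.0, abs=1e-12)


class TestSolveConserved:
    def test_zero_coregulator_total_zeroes_c_species(self, unit_params):
        sol = solve_conserved(unit_params, {"L": 1e-8, "C": 0.0, "D": 1e-8, "R": 1e-9})
        for s in ("RC", "LRC", "RCD", "LRCD"):
            assert sol.species[s] == 0.0

    def test_excess_partners_match_analytic_mode(self, unit_params):
        rtot = 1e-12
        totals = {"L": 1e-8, "C": 2e-8, "D": 5e-9, "R": rtot}
        sol = solve_conserved(unit_params, totals)
        analytic = species_fractions(
            unit_params, Milieu(L=totals["L"], C=totals["C"], D=totals["D"], Rtot=rtot)
        ).as_array()
        numeric = sol.fractions().as_array()
        assert np.allclose(numeric, analytic, rtol=1e-3)

    def test_vanishing_receptor_leaves_partners_undepleted(self, unit_params):
        totals = {"L": 1e-8, "C": 1e-8, "D": 1e-8, "R": 1e-20}
        sol = solve_conserved(unit_params, totals)
        for k in ("L", "C", "D"):
            assert sol.free[k] == pytest.approx(totals[k], rel=1e-9)

    def test_mass_balance_and_mass_action_hold(self):
        # strongly depleted regime: partner totals comparable to receptor
        p = EquilibriumParams(Ka=1e9, Kc=1e9, Kd=1e9, alpha=3.0, beta=0.5, gamma=2.0, delta=4.0)
        totals = {"L": 2e-9, "C": 1e-9, "D": 3e-9, "R": 1e-9}
        sol = solve_conserved(p, totals)
        assert sol.residual < 1e-9
        s, free = sol.species, sol.free
        # law of mass action on representative edges of the cube
        assert s["LR"] / (s["R"] * free["L"]) == pytest.approx(p.Ka, rel=1e-6)
        assert s["RC"] / (s["R"] * free["C"]) == pytest.approx(p.Kc, rel=1e-6)
        assert s["LRC"] / (s["LR"] * free["C"]) == pytest.approx(p.alpha * p.Kc, rel=1e-6)
        assert s["LRCD"] / (s["RCD"] * free["L"]) == pytest.approx(
            p.alpha * p.gamma * p.delta * p.Ka, rel=1e-6
        )

    def test_negative_totals_rejected(self, unit_params):
        with pytest.raises(ValueError):
            solve_conserved(unit_params, {"L": -1e-9, "C": 0, "D": 0, "R": 1e-9})
        with pytest.raises(ValueError):
            solve_conserved(unit_params, {"L": 0, "C": 0, "D": 0, "R": 0})


def brute_force_two_ligand(shared, lig1, lig2, milieu):
    """Independent enumeration of all 12 species weights."""
    kc, kd = shared.Kc * milieu.C, shared.Kd * milieu.D
    b = shared.beta
    w = {"R": 1.0, "RC": kc, "RD": kd, "RCD": b * kc * kd}
    for lg in (lig1, lig2):
        kl = lg.Ka * lg.L
        w[f"LR[{lg.name}]"] = kl
        w[f"LRC[{lg.name}]"] = lg.alpha * kl * kc
        w[f"LRD[{lg.name}]"] = lg.gamma * kl * kd
        w[f"LRCD[{lg.name}]"] = lg.alpha * b * lg.gamma * lg.delta * kl * kc * kd
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


class TestMultiLigand:
    def test_absent_second_ligand_reduces_to_single_ligand_model(self, unit_params, unit_milieu):
        lig1 = LigandParams(name="A", Ka=unit_params.Ka, L=unit_milieu.L)
        lig2 = LigandParams(name="B", Ka=1e8, alpha=3.0, L=0.0)
        fr = multi_ligand_fractions(unit_params, [lig1, lig2], unit_milieu)
        single = species_fractions(unit_params, unit_milieu)
        mapping = {"R": "R", "RC": "RC", "RD": "RD", "RCD": "RCD",
                   "LR[A]": "LR", "LRC[A]": "LRC", "LRD[A]": "LRD", "LRCD[A]": "LRCD"}
        for ext, base in mapping.items():
            assert fr[ext] == pytest.approx(single[base], rel=1e-12, abs=1e-15)
        for sp in ("LR[B]", "LRC[B]", "LRD[B]", "LRCD[B]"):
            assert fr[sp] == 0.0

    def test_split_dose_symmetry(self, unit_params, unit_milieu):
        L = unit_milieu.L
        one = multi_ligand_fractions(
            unit_params, [LigandParams(name="A", Ka=unit_params.Ka, L=L)], unit_milieu
        )
        two = multi_ligand_fractions(
            unit_params,
            [
                LigandParams(name="A", Ka=unit_params.Ka, L=L / 2),
                LigandParams(name="B", Ka=unit_params.Ka, L=L / 2),
            ],
            unit_milieu,
        )
        for sp in ("R", "RC", "RD", "RCD"):
            assert two[sp] == pytest.approx(one[sp], rel=1e-12)
        for sp in ("LR", "LRC", "LRD", "LRCD"):
            assert two[f"{sp}[A]"] + two[f"{sp}[B]"] == pytest.approx(one[f"{sp}[A]"], rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            shared = random_params(rng)
            milieu = random_milieu(rng)
            ligs = [
                LigandParams(
                    name=n,
                    Ka=10.0 ** rng.uniform(6, 10),
                    alpha=10.0 ** rng.uniform(-2, 2),
                    gamma=10.0 ** rng.uniform(-2, 2),
                    delta=10.0 ** rng.uniform(-2, 2),
                    L=10.0 ** rng.uniform(-12, -5),
                )
                for n in ("A", "B")
            ]
            fr = multi_ligand_fractions(shared, ligs, milieu)
            oracle = brute_force_two_ligand(shared, ligs[0], ligs[1], milieu)
            assert fr.keys() == oracle.keys()
            for k in fr:
                assert fr[k] == pytest.approx(oracle[k], abs=1e-12)
            assert abs(sum(fr.values()) - 1.0) < 1e-12

    def test_duplicate_names_rejected(self, unit_params, unit_milieu):
        ligs = [LigandParams(name="A", Ka=1e9, L=1e-9)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            multi_ligand_fractions(unit_params, ligs, unit_milieu)


class TestTranscriptionalResponse:
    def test_no_ligand_no_rcd_coefficient_gives_zero(self, unit_params, unit_milieu):
        dist = species_fractions(unit_params, unit_milieu.replace(L=0.0))
        assert transcriptional_response(dist, ResponseSpec(), 1.0) == 0.0

    def test_linear_in_rtot(self, unit_params, unit_milieu, default_spec):
        dist = species_fractions(unit_params, unit_milieu)
        r1 = transcriptional_response(dist, default_spec, 1.0)
        assert transcriptional_response(dist, default_spec, 2.0) == pytest.approx(2 * r1, rel=1e-15)

    def test_two_ninths_substitution(self, unit_params, unit_milieu):
        dist = species_fractions(unit_params.replace(delta=2.0), unit_milieu)
        assert transcriptional_response(dist, ResponseSpec(), 1.0) == pytest.approx(2 / 9, rel=1e-12)

    def test_rcd_coefficient_enables_basal_activity(self, unit_params, unit_milieu):
        dist = species_fractions(unit_params, unit_milieu.replace(L=0.0))
        spec = ResponseSpec(coefficients={"LRCD": 1.0, "RCD": 0.5})
        assert transcriptional_response(dist, spec, 1.0) == pytest.approx(0.5 * dist["RCD"], rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_response_nondecreasing_in_ligand(self, seed):
        # with the default spec the LRCD fraction is hyperbolic in L
        rng = np.random.default_rng(seed)
        p, m = random_params(rng), random_milieu(rng)
        doses = np.geomspace(1e-13, 1e-4, 12)
        spec = ResponseSpec()
        resp = [
            transcriptional_response(species_fractions(p, m.replace(L=float(d))), spec, m.Rtot)
            for d in doses
        ]
        assert np.all(np.diff(resp) >= -1e-15 * max(resp))
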