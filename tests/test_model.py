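"""Closed-form solutions, micro/macro conversions and the ODE oracle."""

from __future__ import annotations

import json

import numpy as np
import pytest

from nasalpk.exceptions import DegeneratePoleError, InvalidParameterError
from nasalpk.model import (
    DoseRegimen,
    HybridConstants,
    MacroTriexponential,
    MicroParams,
    Route,
    brain_coefficients,
    brain_profile,
    central_macro,
    central_profile,
    hybrid_to_micro_iv,
    micro_to_hybrid,
    ode_simulate,
    params_from_json,
    params_to_json,
)

from conftest import IV_MACRO, IV_MICRO, random_micro, regimen_for


class TestMicroToHybrid:
    def test_reproduces_published_iv_hybrids(self):
        """The reported rat disposition rates yield the reported hybrids."""
        h = micro_to_hybrid(
            MicroParams(k12=IV_MICRO["K12"], k21=IV_MICRO["K21"], k10=IV_MICRO["K10"])
        )
        assert h.lambda1 == pytest.approx(0.1286, abs=2e-4)
        assert h.lambda2 == pytest.approx(0.0031, abs=5e-5)

    def test_decoupled_limit_collapses_to_micro_rates(self):
        h = micro_to_hybrid(MicroParams(k12=0.0, k21=0.01, k10=0.1))
        assert h.lambda1 == pytest.approx(0.1, rel=1e-14)
        assert h.lambda2 == pytest.approx(0.01, rel=1e-14)

    def test_roots_satisfy_characteristic_polynomial(self):
        """Both hybrids are exact roots of s^2 - (K12+K21+K10)s + K21*K10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = random_micro(rng, with_absorption=False)
            h = micro_to_hybrid(m)
            b, c = m.k12 + m.k21 + m.k10, m.k21 * m.k10
            for lam in (h.lambda1, h.lambda2):
                assert abs(lam * lam - b * lam + c) < 1e-12 * max(b * b, 1.0)
            assert h.lambda1 > h.lambda2 > 0

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(InvalidParameterError):
            micro_to_hybrid(MicroParams(k12=0.1, k21=0.0, k10=0.1))


class TestHybridToMicroIV:
    def test_published_iv_chain(self, iv_macro_printed):
        m = hybrid_to_micro_iv(iv_macro_printed)
        assert m.k21 == pytest.approx(0.0146, abs=1e-4)
        assert m.k10 == pytest.approx(0.0275, rel=0.02)
        assert m.k12 == pytest.approx(0.0897, rel=0.02)

    def test_vanishing_slow_coefficient_degenerates_correctly(self):
        """C3 -> 0: a single observable phase gives K21 -> lambda2, K10 -> lambda1."""
        macro = MacroTriexponential(0.0, 100.0, 1e-9, 0.0, 0.2, 0.01, n_terms=2)
        m = hybrid_to_micro_iv(macro)
        assert m.k21 == pytest.approx(0.01, rel=1e-6)
        assert m.k10 == pytest.approx(0.2, rel=1e-6)

    def test_round_trip_with_closed_form_coefficients(self):
        """micro -> IV closed-form coefficients -> inversion recovers the micros."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_micro(rng, with_absorption=False)
            macro = central_macro(m, regimen_for(m))
            rec = hybrid_to_micro_iv(macro)
            assert rec.k10 == pytest.approx(m.k10, rel=1e-8)
            assert rec.k12 == pytest.approx(m.k12, rel=1e-8)
            assert rec.k21 == pytest.approx(m.k21, rel=1e-8)

    def test_rejects_nonpositive_coefficients(self):
        macro = MacroTriexponential(0.0, -1.0, 2.0, 0.0, 0.2, 0.01, n_terms=2)
        with pytest.raises(InvalidParameterError):
            hybrid_to_micro_iv(macro)


class TestCentralProfile:
    def test_intranasal_starts_at_zero(self):
        rng = np.random.default_rng(0)
        m = random_micro(rng)
        c = central_profile(m, regimen_for(m), [0.0])
        assert abs(c[0]) < 1e-9 * m.require_v1()

    def test_iv_starts_at_dose_over_v1(self):
        m = MicroParams(0, 0, 0.0897, 0.0146, 0.0275, v1=276.0)
        reg = DoseRegimen(100_000.0, Route.IV_BOLUS)
        c = central_profile(m, reg, [0.0])
        assert c[0] == pytest.approx(100_000.0 / 276.0, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_ode_oracle_intranasal(self, seed):
        """Closed form and numerical integration agree to 1e-6 sup-norm."""
        rng = np.random.default_rng(seed)
        m = random_micro(rng)
        reg = regimen_for(m)
        lam2 = micro_to_hybrid(m).lambda2
        t = np.linspace(0.0, 10.0 / lam2, 400)
        closed = central_profile(m, reg, t)
        traj = ode_simulate(m, reg, t)
        err = np.max(np.abs(traj.concentration(m.v1) - closed)) / np.max(closed)
        assert err < 1e-6

    def test_iv_biexponential_against_ode(self):
        """The bolus biexponential agrees with the independent ODE solution."""
        m = MicroParams(0, 0, 0.0897, 0.0146, 0.0275, v1=276.0)
        reg = DoseRegimen(100_000.0, Route.IV_BOLUS)
        t = np.linspace(0.0, 1000.0, 500)
        closed = central_profile(m, reg, t)
        traj = ode_simulate(m, reg, t)
        err = np.max(np.abs(traj.concentration(276.0) - closed)) / closed.max()
        assert err < 1e-6
        macro = central_macro(m, reg)
        # coefficients of the bolus solution are positive and sum to C(0)
        assert macro.coeff_fast > 0 and macro.coeff_slow > 0
        assert macro.coeff_fast + macro.coeff_slow == pytest.approx(
            reg.dose_ng / 276.0, rel=1e-12
        )

    def test_degenerate_absorption_pole_rejected(self):
        disp = MicroParams(0, 0, 0.0897, 0.0146, 0.0275)
        lam1 = micro_to_hybrid(disp).lambda1
        m = MicroParams(lam1, 0.0, 0.0897, 0.0146, 0.0275, v1=100.0)
        with pytest.raises(DegeneratePoleError):
            central_macro(m, DoseRegimen(1e5, Route.INTRANASAL, 0.5))

    def test_rate_ordering_asserted(self):
        """Ka below lambda1 (flip-flop) is rejected loudly, never silently."""
        m = MicroParams(0.001, 0.001, 0.0897, 0.0146, 0.0275, v1=100.0)
        with pytest.raises(InvalidParameterError):
            central_macro(m, DoseRegimen(1e5, Route.INTRANASAL, 0.5))


class TestBrainProfile:
    def test_no_entry_routes_means_zero_brain(self):
        m = MicroParams(0.2, 0.0, 0.0, 0.05, 0.1, v1=100.0)
        x = brain_profile(m, DoseRegimen(1e5, Route.INTRANASAL, 0.5), np.linspace(0, 100, 11))
        assert np.allclose(x, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_micro(rng)
        reg = regimen_for(m)
        lam2 = micro_to_hybrid(m).lambda2
        t = np.linspace(0.0, 10.0 / lam2, 400)
        closed = brain_profile(m, reg, t)
        traj = ode_simulate(m, reg, t)
        err = np.max(np.abs(traj.x_brain - closed)) / np.max(closed)
        assert err < 1e-6

    def test_iv_brain_against_ode(self):
        m = MicroParams(0, 0, 0.0897, 0.0146, 0.0275, v1=276.0)
        reg = DoseRegimen(100_000.0, Route.IV_BOLUS)
        t = np.linspace(0.0, 600.0, 300)
        closed = brain_profile(m, reg, t)
        traj = ode_simulate(m, reg, t)
        assert np.max(np.abs(traj.x_brain - closed)) / closed.max() < 1e-6

    def test_residues_sum_to_zero(self):
        """X2(0) = 0 forces the partial-fraction coefficients to cancel."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            m = random_micro(rng)
            coeffs, _rates = brain_coefficients(m, regimen_for(m))
            scale = np.max(np.abs(coeffs))
            assert abs(coeffs.sum()) < 1e-9 * max(scale, 1.0)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        m = random_micro(rng)
        x = brain_profile(m, regimen_for(m), np.linspace(0, 2000, 500))
        assert np.all(x > -1e-9 * np.max(x))


class TestOdeSimulate:
    def test_one_compartment_closed_form(self):
        """With only elimination active, the bolus decays as dose*exp(-K10 t)."""
        m = MicroParams(0, 0, 0.0, 1e-9, 0.05, v1=10.0)
        reg = DoseRegimen(1000.0, Route.IV_BOLUS)
        t = np.linspace(0, 200, 101)
        traj = ode_simulate(m, reg, t)
        assert np.allclose(traj.x_central, 1000.0 * np.exp(-0.05 * t), rtol=1e-7)

    def test_mass_balance(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            m = random_micro(rng)
            reg = regimen_for(m)
            t = np.linspace(0, 500, 100)
            traj = ode_simulate(m, reg, t)
            assert np.max(np.abs(traj.total - reg.absorbed_ng)) < 1e-8 * reg.absorbed_ng
            assert np.all(np.diff(traj.x_depot) <= 1e-12 * reg.absorbed_ng)

    def test_everything_eventually_eliminated(self):
        rng = np.random.default_rng(33)
        m = random_micro(rng)
        reg = regimen_for(m)
        lam2 = micro_to_hybrid(m).lambda2
        t = np.array([0.0, 40.0 / lam2])
        traj = ode_simulate(m, reg, t)
        assert traj.eliminated[-1] == pytest.approx(reg.absorbed_ng, rel=1e-6)

    def test_requires_time_origin(self):
        m = MicroParams(0, 0, 0.01, 0.01, 0.05, v1=10.0)
        with pytest.raises(InvalidParameterError):
            ode_simulate(m, DoseRegimen(1.0, Route.IV_BOLUS), [5.0, 10.0])


class TestAnalyticAuc:
    def test_matches_integrated_ode(self):
        """Sum(C_i/rate_i) equals the numerically integrated, extrapolated AUC."""
        rng = np.random.default_rng(8)
        m = random_micro(rng)
        reg = regimen_for(m)
        macro = central_macro(m, reg)
        lam2 = micro_to_hybrid(m).lambda2
        t = np.linspace(0.0, 14.0 / lam2, 20000)
        traj = ode_simulate(m, reg, t)
        c = traj.concentration(m.v1)
        # terminal slope estimated from the simulated tail itself
        k_tail = -(np.log(c[-1]) - np.log(c[-2])) / (t[-1] - t[-2])
        auc_num = np.trapezoid(c, t) + c[-1] / k_tail
        assert macro.analytic_auc() == pytest.approx(auc_num, rel=1e-4)


class TestSerialization:
    def test_json_round_trip(self):
        m = MicroParams(0.0489, 0.0623, 0.0697, 0.0107, 0.0275, v1=276.0, v2=1.8)
        reg = DoseRegimen(100_000.0, Route.INTRANASAL, 0.479, body_mass_kg=0.275)
        doc = params_to_json(m, reg)
        keys = set(json.loads(doc))
        assert {"Ka1", "Ka2", "K12", "K21", "K10", "V1", "V2", "F", "dose_ng", "route"} <= keys
        m2, reg2 = params_from_json(doc)
        assert m2 == m
        assert reg2.dose_ng == reg.dose_ng and reg2.bioavailability_f == reg.bioavailability_f

    def test_trajectory_csv_schema(self, tmp_path):
        m = MicroParams(0, 0, 0.0897, 0.0146, 0.0275, v1=276.0)
        traj = ode_simulate(m, DoseRegimen(1e5, Route.IV_BOLUS), np.linspace(0, 60, 7))
        path = tmp_path / "traj.csv"
        traj.to_csv(path, v1=276.0)
        header = path.read_text().splitlines()[0]
        assert header == (
            "time_min,x_depot_ng,x_central_ng,x_brain_ng,eliminated_ng,c_central_ng_per_ml"
        )


class TestValidation:
    def test_macro_requires_rate_ordering(self):
        with pytest.raises(InvalidParameterError):
            MacroTriexponential(-1.0, 2.0, 1.0, 0.05, 0.1, 0.01, n_terms=3)

    def test_hybrid_requires_positive_rates(self):
        with pytest.raises(InvalidParameterError):
            HybridConstants(0.1, -0.01)

    def test_regimen_iv_fixes_bioavailability(self):
        with pytest.raises(InvalidParameterError):
            DoseRegimen(1e5, Route.IV_BOLUS, bioavailability_f=0.5)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            MicroParams(ka1=-0.1, k10=0.1)
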