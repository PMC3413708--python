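"""Core model: right-hand sides, forward simulation, events, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from senpop.analysis import arrest_eigenvalue
from senpop.model_core import (
    LN2,
    CellStateVector,
    FShape,
    ModelParameters,
    constant_growth_rhs,
    default_f_shape,
    pcs_rhs,
    simulate,
    simulate_constant_growth,
    state_fractions,
    stress_response_rhs,
)
from senpop.stress import MINUTES, StressProtocol

from conftest import rk4

rates = st.floats(0.0, 10.0)


# ---------------------------------------------------------------------------
# constant growth (single-rate exponential)
# ---------------------------------------------------------------------------

class TestConstantGrowth:
    def test_rhs_is_r_times_p(self):
        p = ModelParameters(r=0.46, f1=0, f2=0, f3=0)
        assert constant_growth_rhs(CellStateVector(P=100.0), p) == pytest.approx(46.0)

    def test_fast_line_reaches_ten_doublings_in_ten_days(self):
        res = simulate_constant_growth(0.70, P0=1.0, times=[0.0, 10.0])
        assert res.pd[-1] == pytest.approx(0.70 * 10 / LN2, rel=1e-12)
        assert round(res.pd[-1], 1) == 10.1

    def test_zero_rate_is_flat(self):
        res = simulate_constant_growth(0.0, P0=5.0, times=[0.0, 3.0, 9.0])
        assert np.all(res.P == 5.0)
        assert np.all(res.pd == 0.0)

    def test_time_to_first_doubling(self):
        # PD reaches 1 exactly at ln2 / r
        t_double = LN2 / 0.28
        assert t_double == pytest.approx(2.476, abs=5e-4)
        res = simulate_constant_growth(0.28, times=[0.0, t_double])
        assert res.pd[-1] == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------

class TestPcsRhs:
    def test_unstressed_pure_proliferation(self):
        p = ModelParameters(r=0.46, f1=3.8, f2=16.0, f3=0.26)
        dP, dC, dS, dF = pcs_rhs(CellStateVector(P=100.0), p, gamma_now=0.0)
        assert dP == pytest.approx(46.0)
        assert dC == 0.0 and dS == 0.0 and dF == 0.0

    def test_direct_substitution_with_arrested_pool(self):
        # P=0, C=10, F=0: dC = -(f2+f3)*C, dS = f3*C, dP = f2*C
        p = ModelParameters(r=0.46, f1=1.0, f2=16.0, f3=0.26)
        dP, dC, dS, _ = pcs_rhs(CellStateVector(P=0.0, C=10.0), p, gamma_now=0.0)
        assert dC == pytest.approx(-162.6)
        assert dS == pytest.approx(2.6)
        assert dP == pytest.approx(160.0)

    def test_negative_stress_rejected(self):
        p = ModelParameters(r=0.5, f1=1, f2=1, f3=1)
        with pytest.raises(ValueError):
            pcs_rhs(CellStateVector(P=1.0), p, gamma_now=-1.0)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            CellStateVector(P=-1.0)

    @given(P=rates, C=rates, S=rates, F=rates, r=rates, f1=rates,
           f2=rates, f3=rates, gamma=rates)
    def test_mass_exchange_is_conservative(self, P, C, S, F, r, f1, f2, f3, gamma):
        # the f-fluxes cancel pairwise: d(P+C+S)/dt = r*P exactly
        p = ModelParameters(r=r, f1=f1, f2=f2, f3=f3)
        dP, dC, dS, _ = pcs_rhs(CellStateVector(P=P, C=C, S=S, F=F), p, gamma)
        assert dP + dC + dS == pytest.approx(r * P, rel=1e-12, abs=1e-12)

    def test_saturated_arrest_still_has_positive_dominant_eigenvalue(self):
        # irreversible arrest cannot come from the eigenvalue sign alone:
        # even at Fhat=1 this parameter set grows asymptotically, so the
        # high-dose arrest must arise from the extinction event
        p = ModelParameters(r=0.46, f1=3.8, f2=16.0, f3=0.26)
        assert arrest_eigenvalue(p, fhat=1.0) > 0


# ---------------------------------------------------------------------------
# stress response dynamics
# ---------------------------------------------------------------------------

class TestStressResponse:
    def test_unstressed_origin_is_a_fixed_point(self):
        assert stress_response_rhs(0.0, 0.0, 1.0, default_f_shape()) == 0.0

    @pytest.mark.parametrize(
        "shape, expected_count",
        [
            (default_f_shape(1.0), 1),          # a/(c*b) = 1.9 < 2: only F=0
            (FShape(a=2.5, b=0.5, c=2.0), 3),   # a/(c*b) = 2.5 > 2: bistable at rest
        ],
    )
    def test_fixed_point_count_at_zero_stress(self, shape, expected_count):
        F_grid = np.linspace(0.0, 2.0, 20001)
        vals = np.array([stress_response_rhs(F, 0.0, 1.0, shape) for F in F_grid])
        crossings = int(np.sum(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0))
        exact_interior = int(np.sum(vals[1:] == 0.0))
        assert crossings + exact_interior + 1 == expected_count  # +1: root at F=0

    def test_middle_fixed_point_is_unstable_in_bistable_regime(self):
        shape = FShape(a=2.5, b=0.5, c=2.0)
        # roots of c*F = a*F^2/(b^2+F^2), i.e. F^2 - (a/c) F + b^2 = 0
        disc = math.sqrt((shape.a / shape.c) ** 2 - 4 * shape.b**2)
        mid = ((shape.a / shape.c) - disc) / 2
        high = ((shape.a / shape.c) + disc) / 2
        eps = 1e-6

        def h(F):
            return stress_response_rhs(F, 0.0, 1.0, shape)

        assert h(mid + eps) > 0 and h(mid - eps) < 0    # repelling
        assert h(high + eps) < 0 and h(high - eps) > 0  # attracting

    def test_up_switch_is_much_faster_than_relaxation(self):
        # strong step on, then off: 10-90% rise vs 90-10% fall
        p = ModelParameters(r=0.0, f1=0.0, f2=0.0, f3=0.0)
        prot = StressProtocol(kind="pulse", gamma=500.0, pulse_start=0.5,
                              pulse_duration=0.25)
        grid = np.linspace(0.0, 25.0, 10001)
        res = simulate(p, prot, CellStateVector(P=1.0), grid=grid)
        F, t = res.F, grid
        F_max = F.max()
        on = t >= 0.5
        t_rise = (t[on & (F >= 0.9 * F_max)][0] - t[on & (F >= 0.1 * F_max)][0])
        i_peak = int(F.argmax())
        fall, tf = F[i_peak:], t[i_peak:]
        t_fall = tf[fall <= 0.1 * F_max][0] - tf[fall <= 0.9 * F_max][0]
        assert t_fall >= 5.0 * t_rise
        assert F[-1] < 1e-4  # full recovery to the healthy state


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_reduces_to_single_rate_exponential_without_stress(self):
        p = ModelParameters(r=0.46, f1=3.8, f2=16.0, f3=0.26)
        grid = np.linspace(0.0, 10.0, 51)
        res = simulate(p, StressProtocol(kind="none"),
                       CellStateVector(P=1e5), grid=grid)
        np.testing.assert_allclose(res.pd, 0.46 * grid / LN2, rtol=1e-6, atol=1e-9)
        assert res.pd[0] == 0.0

    def test_high_dose_fires_extinction_event_and_pd_plateaus(self, wi38_irr):
        prot = wi38_irr.protocols[2]  # 13.5 min pulse at gamma = 2,800
        res = simulate(wi38_irr.params, prot, wi38_irr.initial, grid=wi38_irr.grid)
        assert res.terminated
        assert 1.0 < res.t_extinction < 1.5
        # permanent plateau after the event
        after = res.times > res.t_extinction
        np.testing.assert_allclose(res.pd[after], res.pd[after][0], rtol=1e-9)
        # but senescence keeps accumulating
        assert res.S[-1] > res.S[np.argmax(after)]

    def test_low_dose_delays_growth_then_recovers(self, wi38_irr):
        prot = wi38_irr.protocols[1]  # 108 s pulse
        res = simulate(wi38_irr.params, prot, wi38_irr.initial, grid=wi38_irr.grid)
        assert not res.terminated
        ctrl = simulate(wi38_irr.params, wi38_irr.protocols[0], wi38_irr.initial,
                        grid=wi38_irr.grid)
        # delayed by roughly a day overall ...
        assert 0.5 < ctrl.pd[-1] - res.pd[-1] < 2.0
        # ... but the final slope is back within 10% of the unstressed slope
        slope = (res.pd[-1] - res.pd[-2]) / (res.times[-1] - res.times[-2])
        assert slope == pytest.approx(wi38_irr.params.r / LN2, rel=0.10)

    def test_production_solver_matches_rk4_oracle(self):
        p = ModelParameters(r=0.46, f1=3.8, f2=16.0, f3=0.26)
        prot = StressProtocol(kind="constant", gamma=0.5)
        grid = np.array([0.0, 0.5, 1.0])
        res = simulate(p, prot, CellStateVector(P=100.0), grid=grid)

        def rhs(t, y):
            P, C, S, F = y
            fhat = F / p.K
            a, b, c = p.f_shape.a, p.f_shape.b, p.f_shape.c
            return (p.r * P - p.f1 * fhat * P + p.f2 * C,
                    p.f1 * fhat * P - (p.f2 + p.f3) * C,
                    p.f3 * C,
                    0.5 + a * F * F / (b * b + F * F) - c * F)

        oracle = rk4(rhs, [100.0, 0.0, 0.0, 0.0], grid, dt=1e-4)
        for got, want in zip((res.P, res.C, res.S, res.F), oracle):
            np.testing.assert_allclose(got[1:], want[1:], rtol=1e-6, atol=1e-8)

    def test_trajectory_conserves_mass_and_monotone_s(self, wi38_irr, wi38_rep):
        # total(t) - total(0) must equal the integral of r*P: the arrest
        # fluxes only move mass between compartments
        cases = [
            (wi38_irr, wi38_irr.protocols[1], np.arange(0.0, 6.005, 0.01), 1e-4),
            (wi38_rep, wi38_rep.protocols[0], wi38_rep.grid, 1e-5),
        ]
        for fx, prot, grid, tol in cases:
            res = simulate(fx.params, prot, fx.initial, grid=grid)
            assert not res.terminated
            for comp in (res.P, res.C, res.S, res.F):
                assert np.all(comp >= -1e-9)
            assert np.all(np.diff(res.S) >= -1e-9)  # no back reaction from S
            dtotal = np.trapezoid(fx.params.r * res.P, grid)
            assert res.total[-1] - res.total[0] == pytest.approx(dtotal, rel=tol)

    def test_errors(self):
        p = ModelParameters(r=0.5, f1=1, f2=1, f3=1)
        with pytest.raises(ValueError):
            simulate(p, StressProtocol(kind="none"))  # no horizon
        with pytest.raises(ValueError):
            simulate(p, StressProtocol(kind="none"),
                     CellStateVector(P=0.0, F=0.5), t_end=1.0)  # empty population
        with pytest.raises(ValueError):
            simulate(p, StressProtocol(kind="none"), t_end=1.0,
                     grid=[0.0, 2.0, 1.0])  # non-monotone grid


class TestStateFractions:
    def test_pure_p_trajectory(self):
        p = ModelParameters(r=0.3, f1=0.0, f2=0.0, f3=0.0)
        res = simulate(p, StressProtocol(kind="none"), CellStateVector(P=10.0),
                       t_end=5.0)
        fr = state_fractions(res)
        np.testing.assert_allclose(fr["P"], 1.0, atol=1e-12)
        np.testing.assert_allclose(fr["C+S"], 0.0, atol=1e-12)

    def test_fractions_sum_to_one(self, wi38_rep):
        res = simulate(wi38_rep.params, wi38_rep.protocols[0], wi38_rep.initial,
                       grid=wi38_rep.grid)
        fr = state_fractions(res)
        np.testing.assert_allclose(fr["P"] + fr["C"] + fr["S"], 1.0, atol=1e-9)

    def test_s_fraction_monotone_when_total_is_constant(self):
        # with r=0 the total is constant while S never decreases
        p = ModelParameters(r=0.0, f1=2.0, f2=1.0, f3=0.5)
        res = simulate(p, StressProtocol(kind="constant", gamma=1.0),
                       CellStateVector(P=100.0), t_end=20.0,
                       extinction_threshold=0.0)
        fr = state_fractions(res)
        assert np.all(np.diff(fr["S"]) >= -1e-9)

    def test_replicative_end_state_is_senescent(self, wi38_rep):
        res = simulate(wi38_rep.params, wi38_rep.protocols[0], wi38_rep.initial,
                       grid=wi38_rep.grid)
        assert state_fractions(res)["S"][-1] > 0.95
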