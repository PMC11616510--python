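"""Kinetic rate laws, in-cell integration and the cells-in-series column."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnztreat import (CellState, KineticParameters, ReactorConfig, mn_rate,
                      plugflow_outlet, simulate, simulate_schedule,
                      step_reaction, zn_rate)
from mnztreat.exceptions import ValidationError
from mnztreat.transport import MM_MN, SECONDS_PER_DAY


class TestRateLaws:
    def test_mn_rate_zero_substrate(self):
        assert mn_rate(0.0, KineticParameters(k1=1e-4)) == 0.0

    def test_mn_rate_first_order_product(self):
        p = KineticParameters(k1=1.03e-4)
        c = 19.0 / MM_MN / 1000.0  # 19 mg/L in mol/L
        assert mn_rate(c, p) == pytest.approx(1.03e-4 * c)
        assert mn_rate(c, p) == pytest.approx(3.562e-8, rel=1e-3)

    def test_mn_rate_inert_when_constants_zero(self):
        p = KineticParameters(k1=0.0, k2=0.0)
        assert mn_rate(1e-3, p, c_mnox=1e-3) == 0.0

    def test_mn_rate_autocatalytic_term(self):
        p = KineticParameters(k1=0.0, k2=2.0)
        assert mn_rate(1e-4, p, c_mnox=1e-3) == pytest.approx(2.0 * 1e-3 * 1e-4)

    def test_mn_rate_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            mn_rate(-1e-9, KineticParameters())

    def test_zn_rate_equilibrium_is_zero(self):
        p = KineticParameters(km=1e-3, kd=4.49)
        c = 1e-4
        assert zn_rate(c, p.kd * c, p) == pytest.approx(0.0, abs=1e-20)

    def test_zn_rate_empty_sorbent_sorbs(self):
        p = KineticParameters(km=1e-3, kd=4.49)
        assert zn_rate(2e-4, 0.0, p) == pytest.approx(1e-3 * 2e-4)

    def test_zn_rate_desorbs_when_overloaded(self):
        p = KineticParameters(km=1e-3, kd=4.49)
        assert zn_rate(0.0, 1e-5, p) < 0

    def test_zn_rate_zero_kd_with_load_rejected(self):
        p = KineticParameters(km=1e-3, kd=0.0)
        with pytest.raises(ValidationError):
            zn_rate(1e-4, 1e-5, p)


class TestStepReaction:
    def test_zero_parameters_leave_state_unchanged(self):
        cell = CellState(c_mn=1e-4, c_zn=2e-4, s_zn=1e-5, m_solid=1.0)
        p = KineticParameters(k1=0, km=0, kd=4.49)
        out = step_reaction(cell, p, ReactorConfig(), 1e4)
        assert out.c_mn == cell.c_mn and out.c_zn == cell.c_zn
        assert out.s_zn == cell.s_zn

    def test_pure_mn_decay_matches_exponential(self):
        c0 = 19.0 / MM_MN / 1000.0
        cell = CellState(c_mn=c0)
        p = KineticParameters(k1=1.03e-4, km=0)
        out = step_reaction(cell, p, ReactorConfig(), 1e4)
        # 19*exp(-1.03) = 6.78 mg/L
        assert out.c_mn * MM_MN * 1000 == pytest.approx(19 * math.exp(-1.03))
        assert out.c_mn * MM_MN * 1000 == pytest.approx(6.78, abs=5e-3)

    def test_batch_zn_reaches_partition_equilibrium(self):
        # c_eq = c0/(1 + M*Kd) with fixed sorbent mass M
        cfg = ReactorConfig(sorbent_growth=False, initial_sorbent_g_per_l=1.0)
        c0 = 8.0 / 65.38 / 1000.0
        cell = CellState(c_zn=c0, m_solid=1.0)
        p = KineticParameters(k1=0.0, km=1e-3, kd=4.49)
        out = step_reaction(cell, p, cfg, 1e9)
        c_eq = 8.0 / (1 + 1.0 * 4.49)
        assert out.c_zn * 65.38 * 1000 == pytest.approx(c_eq, rel=1e-9)
        assert out.c_zn * 65.38 * 1000 == pytest.approx(1.457, abs=5e-4)
        # sorbed + aqueous Zn is conserved
        assert out.c_zn + out.s_zn * out.m_solid == pytest.approx(c0, rel=1e-12)

    def test_mno2_growth_couples_to_mn_oxidised(self):
        cfg = ReactorConfig(sorbent_growth=True, initial_sorbent_g_per_l=1.0)
        cell = CellState(c_mn=3e-4)
        p = KineticParameters(k1=1e-4, km=0)
        out = step_reaction(cell, p, cfg, 5e3)
        oxidised = cell.c_mn - out.c_mn
        assert out.mno2_cum == pytest.approx(oxidised, rel=1e-12)
        assert out.m_solid == pytest.approx(1.0 + oxidised * 86.94, rel=1e-12)


class TestSimulate:
    def test_steady_outlet_matches_plugflow_hrt_half_day(self, config, field_params):
        r = simulate(config, field_params, (19.0, 0.0), 0.5, 5.0)
        assert r.outlet_mn_mg_l[-1] == pytest.approx(0.222, abs=5e-4)
        assert r.outlet_mn_mg_l[-1] == pytest.approx(
            plugflow_outlet(19.0, field_params.k1, 0.5), rel=1e-12)
        assert r.outlet_mn_mg_l[-1] < 0.5  # below the observed field ceiling

    def test_steady_outlet_matches_plugflow_hrt_03(self, config, field_params):
        r = simulate(config, field_params, (19.0, 0.0), 0.3, 5.0)
        assert r.outlet_mn_mg_l[-1] == pytest.approx(1.31, abs=1e-2)

    def test_zero_rates_delay_inlet_by_one_hrt(self, config):
        inert = KineticParameters(k1=0, km=0, kd=4.49)
        step_day = 3.0

        def inlet(t):
            return (10.0 if t < step_day else 20.0, 5.0)

        r = simulate(config, inert, inlet, 1.0, 6.0)
        # before the step arrives at the outlet (one HRT after step_day)
        before = r.outlet_at(step_day + 0.9, "mn")
        after = r.outlet_at(step_day + 1.1, "mn")
        assert before == pytest.approx(10.0, rel=1e-12)
        assert after == pytest.approx(20.0, rel=1e-12)

    def test_equilibrium_limit_tracks_local_partition(self, config):
        # km large: s_zn/Kd must track c_zn within 0.1 % everywhere
        p = KineticParameters(k1=1.03e-4, km=1.0, kd=4.49)
        r = simulate(config, p, (19.0, 8.0), 0.5, 10.0, snapshot_every=16)
        assert r.snapshots
        for snap in r.snapshots:
            c = snap["c_zn"]
            s_over_kd = snap["u"] / snap["m"] / p.kd
            ok = c > 1e-12
            assert np.allclose(s_over_kd[ok], c[ok], rtol=1e-3)

    def test_outlet_monotone_in_hrt_and_k1(self, config):
        outs_h = [simulate(config, KineticParameters(), (19.0, 0.0), h, 8.0)
                  .outlet_mn_mg_l[-1] for h in (0.2, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(outs_h, outs_h[1:]))
        outs_k = [simulate(config, KineticParameters(k1=k), (19.0, 0.0), 0.5, 5.0)
                  .outlet_mn_mg_l[-1] for k in (1e-5, 5e-5, 1e-4, 5e-4)]
        assert all(a > b for a, b in zip(outs_k, outs_k[1:]))

    def test_zn_outlet_monotone_in_kd_and_sorbent(self, config, field_params):
        outs_kd = [simulate(config, field_params.with_(kd=kd), (19.0, 8.0),
                            0.5, 30.0).outlet_zn_mg_l[-1]
                   for kd in (0.5, 2.0, 4.49, 10.0)]
        assert all(a >= b for a, b in zip(outs_kd, outs_kd[1:]))
        # once the bed saturates the plateau outlet no longer depends on the
        # inventory, so ties at round-off level are expected
        outs_m = [simulate(config.with_(initial_sorbent_g_per_l=m), field_params,
                           (19.0, 8.0), 0.5, 30.0).outlet_zn_mg_l[-1]
                  for m in (0.5, 1.0, 5.0, 20.0)]
        assert all(a >= b - 1e-6 for a, b in zip(outs_m, outs_m[1:]))

    def test_dispersion_smears_but_conserves_mass(self, field_params):
        cfg = ReactorConfig(dispersivity_m=0.2)
        r = simulate(cfg, field_params, (25.0, 9.0), 0.3, 10.0)
        assert r.mn_budget_closure() < 1e-10
        assert r.zn_budget_closure() < 1e-10
        # dispersion lets some water short-circuit: outlet above plug flow
        assert r.outlet_mn_mg_l[-1] > plugflow_outlet(25.0, field_params.k1, 0.3)

    @given(k1=st.floats(0.0, 1e-3), km=st.floats(0.0, 1e-2),
           kd=st.floats(1e-2, 100.0), hrt=st.floats(0.1, 2.0))
    @settings(max_examples=15, deadline=None)
    def test_states_stay_nonnegative_and_budgets_close(self, k1, km, kd, hrt):
        p = KineticParameters(k1=k1, km=km, kd=kd)
        r = simulate(ReactorConfig(n_cells=8), p, (19.0, 8.0), hrt, 5 * hrt)
        assert np.all(r.outlet_mn_mg_l >= 0)
        assert np.all(r.outlet_zn_mg_l >= 0)
        fs = r.final_state
        assert all(np.all(fs[k] >= 0) for k in ("c_mn", "c_zn", "u", "m"))
        assert r.mn_budget_closure() < 1e-9
        assert r.zn_budget_closure() < 1e-9


class TestSimulateSchedule:
    def test_regimes_chain_and_conserve(self, config, field_params):
        spans = [(0.0, 16.0, 2.0), (16.0, 113.0, 0.5), (113.0, 152.0, 0.3)]
        r = simulate_schedule(config, field_params, (19.0, 8.0), spans)
        assert r.mn_budget_closure() < 1e-10
        assert r.zn_budget_closure() < 1e-10
        # outlet inside the middle regime sits at its plug-flow level
        assert r.outlet_at(60.0, "mn") == pytest.approx(
            plugflow_outlet(19.0, field_params.k1, 0.5), rel=1e-9)

    def test_empty_regime_rejected(self, config, field_params):
        with pytest.raises(ValidationError):
            simulate_schedule(config, field_params, (19.0, 8.0),
                              [(0.0, 0.0, 0.5)])


class TestPlugflowOutlet:
    @pytest.mark.parametrize("c_in, k1, hrt, expected", [
        (25.0, 1.03e-4, 0.103, 10.0),  # ln(25/10)/k1 ~ 8,896 s
        (19.0, 1.03e-4, 0.0, 19.0),
        (19.0, 0.0, 5.0, 19.0),
    ])
    def test_closed_form(self, c_in, k1, hrt, expected):
        assert plugflow_outlet(c_in, k1, hrt) == pytest.approx(expected, abs=5e-3)
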