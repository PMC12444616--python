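"""Bioreactor kinetics, discrete tank update, scheduling and the coupled loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubioleach import (
    BioKinetics,
    BioreactorState,
    LoopConfig,
    ProcessSchedule,
    ScheduleEvent,
    bacteria_rhs,
    bioreactor_step,
    default_initial_bioreactor,
    metabolic_rate,
    monod_mu,
    replace_medium,
    run_coupled,
)


class TestMonod:
    def test_zero_substrate_zero_growth(self, bio):
        assert monod_mu(0.0, bio) == 0.0

    def test_half_saturation(self, bio):
        assert monod_mu(bio.k_s_g_l, bio) == pytest.approx(
            bio.mu_max_per_min / 2
        )

    def test_high_substrate_approaches_max(self, bio):
        assert monod_mu(100 * bio.k_s_g_l, bio) == pytest.approx(
            bio.mu_max_per_min * 100 / 101
        )

    @given(st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
    @settings(deadline=None)
    def test_bounded_by_mu_max(self, fe2):
        bio = BioKinetics()
        assert 0.0 <= monod_mu(fe2, bio) <= bio.mu_max_per_min

    def test_negative_substrate_rejected(self, bio):
        with pytest.raises(ValueError):
            monod_mu(-1.0, bio)


class TestBacteriaRhs:
    def test_no_toxicity_high_substrate_is_exponential_growth(self):
        bio = BioKinetics(mu_d_l2_g2_min=0.0, mu_tox_l2_g2_min=0.0)
        state = BioreactorState(n_bacteria=1e9, fe2_g=100 * bio.k_s_g_l)
        dn = bacteria_rhs(state, bio)
        assert dn == pytest.approx(monod_mu(state.fe2_g, bio) * 1e9)

    def test_extinct_population_stays_extinct(self, bio):
        state = BioreactorState(n_bacteria=0.0, fe2_g=5.0, fe3_g=1.0, cu2_g=1.0)
        assert bacteria_rhs(state, bio) == 0.0

    def test_toxicity_balance_point(self):
        # mu = 0.001/min vs mu_tox Cu^2 = 1e-5 * 100 = 1e-3 -> dN/dt = 0
        bio = BioKinetics(
            mu_max_per_min=1.0e-3, k_s_g_l=1e-9,
            mu_d_l2_g2_min=0.0, mu_tox_l2_g2_min=1.0e-5,
        )
        state = BioreactorState(n_bacteria=1e6, fe2_g=10.0, cu2_g=10.0)
        assert bacteria_rhs(state, bio) == pytest.approx(0.0, abs=1e-12 * 1e6)


class TestMetabolicRate:
    def test_zero_population_or_substrate(self, bio):
        assert metabolic_rate(BioreactorState(fe2_g=5.0), bio) == 0.0
        assert metabolic_rate(BioreactorState(n_bacteria=1e9), bio) == 0.0

    def test_matches_trigger_threshold_arithmetic(self):
        # mu = 0.002/min, Y = 1e9 cells/g, N = 2.5e9 cells/L -> 0.005 g/(L min)
        bio = BioKinetics(
            mu_max_per_min=0.002, k_s_g_l=1e-12, yield_cells_per_g=1e9,
        )
        state = BioreactorState(n_bacteria=2.5e9, fe2_g=50.0)
        assert metabolic_rate(state, bio) == pytest.approx(0.005, rel=1e-9)


class TestBioreactorStep:
    def test_idle_tank_is_a_fixed_point(self, bio):
        cfg = LoopConfig(q_ml_min=0.0)
        state = BioreactorState(n_bacteria=0.0, fe2_g=3.0, fe3_g=2.0, cu2_g=1.0)
        out = bioreactor_step(state, (0.0, 0.0, 0.0), cfg, bio)
        assert out == state

    def test_dilution_only_arithmetic(self, bio):
        # C <- 8 * 3.5995 / 3.6 = 7.9989 g/L when the column returns nothing
        cfg = LoopConfig(q_ml_min=5.0, v_bioreactor_l=3.6, dt_min=0.1)
        state = BioreactorState(n_bacteria=0.0, fe3_g=8.0)
        out = bioreactor_step(state, (0.0, 0.0, 0.0), cfg, bio)
        assert out.fe3_g == pytest.approx(7.99888888888, rel=1e-9)

    def test_loop_exchange_conserves_iron(self, bio):
        """Tank + column-bound parcel hold the same Fe before and after."""
        cfg = LoopConfig(q_ml_min=5.0)
        state = BioreactorState(n_bacteria=0.0, fe2_g=3.0, fe3_g=5.0)
        col_out = (0.01, 0.05, 0.08)  # mol/L
        out = bioreactor_step(state, col_out, cfg, bio)
        qdt = cfg.q_ml_min / 1000.0 * cfg.dt_min
        fe_in = (col_out[1] + col_out[2]) * qdt * bio.aw_fe
        fe_out = (state.fe2_g + state.fe3_g) * qdt
        before = (state.fe2_g + state.fe3_g) * cfg.v_bioreactor_l
        after = (out.fe2_g + out.fe3_g) * cfg.v_bioreactor_l
        assert after == pytest.approx(before + fe_in - fe_out, rel=1e-12)

    def test_oxidation_moves_iron_between_pools(self):
        bio = BioKinetics(mu_d_l2_g2_min=0.0, mu_tox_l2_g2_min=0.0)
        cfg = LoopConfig(q_ml_min=0.0)
        state = BioreactorState(n_bacteria=5e9, fe2_g=5.0, fe3_g=1.0)
        out = bioreactor_step(state, (0.0, 0.0, 0.0), cfg, bio)
        assert out.fe2_g < state.fe2_g
        assert out.fe2_g + out.fe3_g == pytest.approx(6.0, rel=1e-12)


class TestReplaceMedium:
    def test_reference_ferric_dilution(self):
        # 2.6 g/L with 80% replaced by Fe3+-free medium -> 0.52 g/L
        state = BioreactorState(n_bacteria=1e9, fe2_g=1.0, fe3_g=2.6, cu2_g=8.0)
        out = replace_medium(state, 0.8, fresh_fe2_g_l=9.4)
        assert out.fe3_g == pytest.approx(0.52)
        assert out.cu2_g == pytest.approx(1.6)

    def test_65_percent_retains_35(self):
        state = BioreactorState(cu2_g=10.0)
        assert replace_medium(state, 0.65).cu2_g == pytest.approx(3.5)

    def test_small_fraction_limit_is_identity(self, bio):
        state = BioreactorState(n_bacteria=1e9, fe2_g=1.0, fe3_g=2.0, cu2_g=3.0)
        out = replace_medium(state, 1e-12, fresh_fe2_g_l=9.4)
        assert out.fe3_g == pytest.approx(state.fe3_g, rel=1e-9)

    def test_cells_removed_proportionally(self):
        state = BioreactorState(n_bacteria=1e9, fe2_g=1.0)
        assert replace_medium(state, 0.8).n_bacteria == pytest.approx(2e8)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.5, 2.0])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ValueError):
            replace_medium(BioreactorState(), fraction)


class TestScheduleValidation:
    def test_exactly_one_timing_required(self):
        with pytest.raises(ValueError):
            ScheduleEvent("stop")
        with pytest.raises(ValueError):
            ScheduleEvent("stop", at_h=1.0, after_h=1.0)

    def test_unknown_action_and_trigger_rejected(self):
        with pytest.raises(ValueError):
            ScheduleEvent("explode", at_h=1.0)
        with pytest.raises(ValueError):
            ScheduleEvent("stop", when={"phase_of_moon": 1})

    def test_flow_actions_need_flow(self):
        with pytest.raises(ValueError):
            ScheduleEvent("set_flow", at_h=1.0)

    def test_reference_schedules_encode_the_replacements(self):
        sim1 = ProcessSchedule.simulation_1()
        sim2 = ProcessSchedule.simulation_2()
        (r1,) = [e for e in sim1.events if e.action == "replace_medium"]
        (r2,) = [e for e in sim2.events if e.action == "replace_medium"]
        assert r1.fraction == 0.8
        assert r2.fraction == 0.65


class TestRunCoupled:
    def test_no_recirculation_means_untouched_column(self, geom, chem, bio,
                                                     loop):
        sched = ProcessSchedule(events=(ScheduleEvent("stop", at_h=24.0),),
                                name="growth")
        res = run_coupled(sched, geom, chem, bio, loop)
        assert np.all(res.col_cu2 == 0.0)
        assert res.col_solid[0] == res.col_solid[-1]
        assert res.efficiency[-1] == 0.0

    def test_growth_phase_oxidizes_the_medium(self, geom, chem, bio, loop):
        sched = ProcessSchedule(events=(ScheduleEvent("stop", at_h=48.0),),
                                name="growth")
        res = run_coupled(sched, geom, chem, bio, loop)
        assert res.fe2_g[-1] < 0.1
        assert res.fe3_g[-1] == pytest.approx(9.4, abs=0.1)

    def test_trigger_determinism(self, geom, chem, bio, loop):
        times = []
        for _ in range(2):
            res = run_coupled(ProcessSchedule.simulation_2(), geom, chem, bio,
                              loop)
            times.append(tuple(e["time_min"] for e in res.events))
        assert times[0] == times[1]

    def test_efficiency_monotone_and_bounded(self, geom, chem, bio, loop):
        res = run_coupled(ProcessSchedule.simulation_1(), geom, chem, bio, loop,
                          max_duration_h=60.0)
        eff = res.efficiency
        assert np.all(np.diff(eff) >= -1e-15)
        assert 0.0 <= eff[-1] <= 1.0

    def test_states_stay_nonnegative(self, geom, chem, bio, loop):
        res = run_coupled(ProcessSchedule.simulation_1(), geom, chem, bio, loop,
                          max_duration_h=120.0)
        for arr in (res.n_bacteria, res.fe2_g, res.fe3_g, res.cu_g,
                    res.col_cu2, res.col_fe3, res.col_fe2, res.col_solid):
            assert np.all(arr >= 0.0)

    def test_unsatisfiable_trigger_stops_at_max_duration(self, geom, chem, bio,
                                                         loop, caplog):
        sched = ProcessSchedule(
            events=(
                ScheduleEvent("start_recirculation", when={"cu_biorea_ge": 1e9},
                              q_ml_min=5.0),
                ScheduleEvent("stop", after_h=1.0),
            ),
            name="never",
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="cubioleach.bioreactor"):
            res = run_coupled(sched, geom, chem, bio, loop, max_duration_h=2.0)
        assert res.times_min[-1] == pytest.approx(120.0)
        assert any("not exhausted" in r.message for r in caplog.records)

    def test_after_event_anchor(self, geom, chem, bio, loop):
        sched = ProcessSchedule(
            events=(
                ScheduleEvent("start_recirculation", at_h=1.0, q_ml_min=5.0),
                ScheduleEvent("set_flow", at_h=2.0, q_ml_min=2.5),
                ScheduleEvent("stop", after_h=1.0,
                              after_event="start_recirculation"),
            ),
            name="anchored",
        )
        res = run_coupled(sched, geom, chem, bio, loop, max_duration_h=10.0)
        assert res.times_min[-1] == pytest.approx(120.0, abs=0.2)

    def test_phase_metrics_partition_the_run(self, geom, chem, bio, loop):
        res = run_coupled(ProcessSchedule.simulation_1(), geom, chem, bio, loop,
                          max_duration_h=120.0)
        phases = res.phase_metrics
        assert phases[0]["t_start_h"] == 0.0
        total = sum(p["duration_h"] for p in phases)
        assert total == pytest.approx(res.times_min[-1] / 60.0)


class TestLoopConservation:
    def test_closed_loop_iron_conserved_eight_days(self, geom, chem, bio, loop):
        """No replacement events: total Fe constant over 8 simulated days."""
        sched = ProcessSchedule(
            events=(
                ScheduleEvent("start_recirculation", at_h=48.0, q_ml_min=5.0),
                ScheduleEvent("stop", at_h=192.0),
            ),
            name="closed",
        )
        res = run_coupled(sched, geom, chem, bio, loop)
        fe = res.total_fe_mol
        assert np.ptp(fe) / fe[0] < 1e-3

    def test_copper_ledger_closes_across_replacements(self, geom, chem, bio,
                                                      loop):
        res = run_coupled(ProcessSchedule.simulation_1(), geom, chem, bio, loop)
        cu = res.total_cu_mol
        assert np.ptp(cu) / cu[0] < 1e-3
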