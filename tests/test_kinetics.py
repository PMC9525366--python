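"""Transport laws, unit conversions, ODE assembly, conservation and
Wolff-Chaikoff gating."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyroblock.kinetics import (
    N_COMP,
    N_STATE,
    RADIO,
    STABLE,
    ExposureScenario,
    _IDX,
    bq_to_umol,
    build_rhs,
    competitive_rate,
    mg_to_umol,
    mm_rate,
    simulate,
)
from thyroblock.parameters import load_parameters


class TestRateLaws:
    def test_zero_substrate_gives_zero(self):
        assert mm_rate(144.9, 63.0, 0.0) == 0.0

    def test_half_saturation(self):
        assert mm_rate(144.9, 63.0, 63.0) == pytest.approx(72.45)

    def test_small_amount_limit_is_first_order(self):
        # far below Km#, T -> (Tmax/Km#) m = k m with k = 2.3
        m = 6.3e-7
        assert mm_rate(144.9, 63.0, m) == pytest.approx(2.3 * m, rel=1e-5)

    def test_rate_never_exceeds_tmax(self):
        for m in (1.0, 63.0, 1e6, 1e12):
            assert mm_rate(144.9, 63.0, m) <= 144.9

    def test_competitive_reduces_to_mm_without_competitor(self):
        for m in (0.01, 63.0, 5000.0):
            assert competitive_rate(144.9, 63.0, m, 0.0) == pytest.approx(
                mm_rate(144.9, 63.0, m)
            )

    def test_competitive_hand_value(self):
        # Tmax*m1/(Km# + m1 + m2) = 144.9*63/189
        assert competitive_rate(144.9, 63.0, 63.0, 63.0) == pytest.approx(48.3)

    def test_strong_inhibition(self):
        m1, m2 = 1e-6, 551.0
        assert competitive_rate(144.9, 63.0, m1, m2) == pytest.approx(
            144.9 * m1 / (63.0 + m1 + m2), rel=1e-12
        )

    @given(
        m1=st.floats(0, 1e4), m2=st.floats(0, 1e4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shared_capacity_symmetry(self, m1, m2):
        total = competitive_rate(144.9, 63.0, m1, m2) + competitive_rate(
            144.9, 63.0, m2, m1
        )
        assert total == pytest.approx(
            mm_rate(144.9, 63.0, m1 + m2), rel=1e-9, abs=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(144.9, 63.0, -1.0)
        with pytest.raises(ValueError):
            competitive_rate(144.9, 63.0, 1.0, -1.0)


class TestConversions:
    def test_one_gram_equivalent(self):
        # the activity of one gram of I-131 corresponds to 1e6/131 umol
        assert bq_to_umol(4.6e15) == pytest.approx(1e6 / 131.0)

    def test_reference_intake(self):
        assert bq_to_umol(700_000.0) == pytest.approx(1.1616e-6, rel=1e-4)

    def test_zero_and_negative(self):
        assert bq_to_umol(0.0) == 0.0
        with pytest.raises(ValueError):
            bq_to_umol(-1.0)

    def test_stable_conversion_matches_saturation_threshold(self):
        # 350 ug of stable iodine is the documented 2.7581 umol
        assert mg_to_umol(0.350) == pytest.approx(2.7581, rel=1e-4)


class TestBuildRhs:
    def test_zero_state_zero_derivative(self):
        rhs = build_rhs(load_parameters(0))
        assert np.all(rhs(0.0, np.zeros(N_STATE)) == 0.0)

    def test_bolus_derivative_hand_assembled(self):
        """Immediately after a blood bolus, the thyroid-iodide inflow is the
        competitive carrier rate and gland efflux/decay terms vanish."""
        params = load_parameters(0)
        rhs = build_rhs(params)
        y = np.zeros(N_STATE)
        m_r, m_s = 1e-6, 100.0
        y[_IDX["blood"]] = m_r
        y[N_COMP + _IDX["blood"]] = m_s
        dy = rhs(0.0, y)
        expected = competitive_rate(144.9, 63.0, m_r, m_s)
        assert dy[_IDX["thyroid_iodide"]] == pytest.approx(expected, rel=1e-12)
        # same carrier, stable species
        assert dy[N_COMP + _IDX["thyroid_iodide"]] == pytest.approx(
            competitive_rate(144.9, 63.0, m_s, m_r), rel=1e-12
        )

    def test_wc_block_zeroes_gland_influx_only(self):
        params = load_parameters(0)
        y = np.zeros(N_STATE)
        y[_IDX["blood"]] = 1.0
        y[_IDX["thyroid_iodide"]] = 0.5
        open_rhs = build_rhs(params, {"maternal": False})(0.0, y)
        blocked = build_rhs(params, {"maternal": True})(0.0, y)
        assert open_rhs[_IDX["thyroid_iodide"]] > 0
        # influx gone, efflux (1.6/d) and decay continue
        lam = params.decay_constant
        assert blocked[_IDX["thyroid_iodide"]] == pytest.approx(
            -(1.6 + lam) * 0.5, rel=1e-12
        )
        # the salivary carrier is never gated
        assert blocked[_IDX["salivary_glands"]] == pytest.approx(
            open_rhs[_IDX["salivary_glands"]]
        )

    def test_unknown_compartment_raises_at_build_time(self):
        params = load_parameters(0)
        bad = replace(
            params, flows=params.flows + (replace(params.flows[0], source="nope"),)
        )
        with pytest.raises(ValueError, match="unknown compartment"):
            build_rhs(bad)


class TestSimulate:
    def test_zero_inputs_zero_trajectory(self):
        traj = simulate(ExposureScenario(week=0, horizon_d=5.0))
        assert np.all(traj.amounts == 0.0)
        assert traj.events == []

    def test_times_strictly_increasing_events_in_range(
        self, traj_week0_blocked_100mg
    ):
        t = traj_week0_blocked_100mg.times
        assert np.all(np.diff(t) > 0) or np.all(np.diff(t) >= 0)
        for ev in traj_week0_blocked_100mg.events:
            assert 0.0 <= ev.t_on_d <= traj_week0_blocked_100mg.scenario.horizon_d

    def test_amounts_nonnegative(self, traj_week0_blocked_100mg):
        assert traj_week0_blocked_100mg.amounts.min() >= -1e-9

    def test_stable_species_conserved(self, traj_week0_blocked_100mg):
        totals = traj_week0_blocked_100mg.amounts[:, :, STABLE].sum(axis=1)
        expected = mg_to_umol(100.0)
        assert np.max(np.abs(totals - expected) / expected) < 1e-6

    def test_radio_balance_with_bodywide_decay(self):
        """With decay in every compartment the live radio total follows
        exp(-lambda t) exactly."""
        params = replace(load_parameters(0), decay_scope="all")
        scen = ExposureScenario(
            week=0, activity_bq=1e6, horizon_d=20.0, wc_enabled=False
        )
        traj = simulate(scen, params)
        total0 = bq_to_umol(1e6)
        live = traj.amounts[:, :, RADIO].sum(axis=1)
        expected = total0 * np.exp(-params.decay_constant * traj.times)
        assert np.max(np.abs(live - expected) / total0) < 1e-6

    def test_radio_balance_with_thyroid_scope_decay(self, traj_week0_unblocked):
        """In the published formulation only gland decays remove radio, so
        live total + gland decay sinks is conserved."""
        traj = traj_week0_unblocked
        total0 = bq_to_umol(traj.scenario.activity_bq)
        live = traj.amounts[:, :, RADIO].sum(axis=1)
        balance = live + traj.sink_maternal + traj.sink_fetal
        assert np.max(np.abs(balance - total0) / total0) < 1e-6

    def test_gland_content_nonincreasing_while_blocked(
        self, traj_week0_blocked_100mg
    ):
        traj = traj_week0_blocked_100mg
        t_on = traj.events[0].t_on_d
        sel = traj.times >= t_on * 1.01
        content = traj.gland_content("maternal", RADIO)[sel] + traj.gland_content(
            "maternal", STABLE
        )[sel]
        assert np.all(np.diff(content) <= 1e-9 * content.max())

    def test_fetal_compartments_empty_before_week_12(self, traj_week0_unblocked):
        for comp in ("fetal_iodide", "fetal_thyroid", "fetal_organic"):
            assert np.all(traj_week0_unblocked.amount(comp, RADIO) == 0.0)

    def test_tolerance_halving_changes_dose_by_less_than_0p1pct(self):
        from thyroblock.dosimetry import total_dose

        scen = ExposureScenario(week=0, activity_bq=7e5, horizon_d=30.0)
        d1 = total_dose(simulate(scen, rtol=1e-8)).dose_maternal_msv
        d2 = total_dose(simulate(scen, rtol=5e-9)).dose_maternal_msv
        assert abs(d1 - d2) / d1 < 1e-3

    def test_week_mismatch_rejected(self):
        with pytest.raises(ValueError):
            simulate(ExposureScenario(week=0), load_parameters(3))

    def test_no_wc_event_for_trace_radioiodine_alone(self, traj_week0_unblocked):
        # 700 kBq is ~0.15 ug of iodine, far below the 350 ug saturation
        assert traj_week0_unblocked.events == []


@given(
    factors=st.lists(
        st.floats(0.5, 2.0), min_size=6, max_size=6
    )
)
@settings(max_examples=8, deadline=None, derandomize=True)
def test_nonnegativity_under_parameter_perturbation(factors):
    """Randomly rescaled carrier capacities never drive any compartment
    negative."""
    params = load_parameters(24)
    mm_flows = [f for f in params.flows if f.law == "michaelis_menten" and f.active]
    new_flows = list(params.flows)
    for f, c in zip(mm_flows, factors):
        new_flows[new_flows.index(f)] = replace(
            f, tmax=f.tmax * c, km_abs=f.km_abs * c
        )
    perturbed = replace(params, flows=tuple(new_flows))
    scen = ExposureScenario(
        week=24, activity_bq=1e6, stable_dose_mg=10.0, horizon_d=2.0
    )
    traj = simulate(scen, perturbed)
    assert traj.amounts.min() >= -1e-9
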