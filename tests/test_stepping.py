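import math

import numpy as np
import pytest

import branchsim as bs
from branchsim.stepping import Event
from conftest import two_soma_network


class TestDetectSpike:
    def test_upward_crossing_fires(self):
        assert bs.detect_spike(-30.0, -10.0, -20.0, 1.5) == 1.5

    def test_downward_crossing_silent(self):
        assert bs.detect_spike(-10.0, -30.0, -20.0, 1.5) is None

    def test_no_retrigger_above_threshold(self):
        assert bs.detect_spike(-10.0, -5.0, -20.0, 1.5) is None


class TestClock:
    def test_invalid_dt_rejected(self):
        with pytest.raises(bs.ConfigurationError):
            bs.SimulationClock(dt=0.0, tstop=1.0)

    def test_t_synch_must_be_multiple_of_dt(self):
        with pytest.raises(bs.ConfigurationError):
            bs.SimulationClock(dt=0.025, tstop=1.0, t_synch=0.06)

    def test_synch_interval_is_min_delay_rounded_down(self):
        clock = bs.SimulationClock(dt=0.025, tstop=1.0)
        assert clock.synch_interval(0.1) == pytest.approx(0.1)
        assert clock.synch_interval(0.26) == pytest.approx(0.25)


class TestSingleCompartmentNumerics:
    def test_resting_equilibrium_is_fixed_point(self):
        """Passive compartment at its leak reversal stays put: drift below
        1e-6 mV over 100 ms (4,000 steps)."""
        model = bs.passive_single_compartment()
        sim = bs.ReferenceSimulation(model, dt=0.025)
        sim.run_steps(4000)
        assert abs(sim.v[0] - (-65.0)) < 1e-6

    def test_rc_charging_matches_analytic(self):
        """C=1 nF, g=0.1 µS, 0.5 nA step: v → -60 mV with τ = 10 ms;
        error < 0.05 mV at t = 50 ms for dt = 0.025 ms."""
        model = bs.passive_single_compartment(amp=0.5, onset=0.0, dur=1e9)
        sim = bs.ReferenceSimulation(model, dt=0.025)
        sim.run_steps(2000)
        analytic = -65.0 + 5.0 * (1.0 - math.exp(-50.0 / 10.0))
        assert abs(sim.v[0] - analytic) < 0.05

    def test_convergence_under_dt_refinement(self):
        """Max-norm error vs the analytic RC curve decreases monotonically
        as dt halves, with observed order >= 1."""
        errors = []
        for dt in (0.2, 0.1, 0.05):
            model = bs.passive_single_compartment(amp=0.5, onset=0.0, dur=1e9)
            sim = bs.ReferenceSimulation(model, dt=dt)
            n = int(round(30.0 / dt))
            errs = []
            for k in range(n):
                sim.step()
                t = (k + 1) * dt
                analytic = -65.0 + 5.0 * (1.0 - math.exp(-t / 10.0))
                errs.append(abs(sim.v[0] - analytic))
            errors.append(max(errs))
        assert errors[0] > errors[1] > errors[2]
        # The voltage update is first-order; its observed order approaches 1
        # from below (0.994 at these dt), so allow finite-dt estimation slack.
        order = math.log2(errors[0] / errors[1])
        assert order >= 0.98

    def test_hh_soma_fires_on_suprathreshold_pulse(self):
        model = bs.hh_soma_model(amp=10.0, onset=2.0, dur=5.0)
        sim = bs.ReferenceSimulation(model, dt=0.025)
        sim.run_steps(int(30.0 / 0.025))
        assert len(sim.spike_times) >= 1
        assert all(2.0 < t < 30.0 for t in sim.spike_times)

    def test_hh_spike_count_stable_under_dt_refinement(self):
        counts = {}
        for dt in (0.025, 0.025 / 8):
            model = bs.hh_soma_model(amp=10.0, onset=2.0, dur=5.0)
            sim = bs.ReferenceSimulation(model, dt=dt)
            sim.run_steps(int(round(30.0 / dt)))
            counts[dt] = len(sim.spike_times)
        assert counts[0.025] == counts[0.025 / 8]

    def test_numerical_blowup_reports_time_and_compartment(self):
        # negative conductance off equilibrium → exponential divergence
        model = bs.passive_single_compartment(g=-10.0, v_init=-60.0)
        sim = bs.ReferenceSimulation(model, dt=0.025)
        with pytest.raises(bs.NumericalBlowupError, match="compartment 0"):
            with np.errstate(over="ignore", invalid="ignore"):
                sim.run_steps(10_000)


class TestEventDelivery:
    def test_delivery_at_first_step_boundary_after_due_time(self):
        """Spike at 0.26 ms + 0.1 ms delay → due 0.36 ms → applied at the
        step starting 0.375 ms (dt = 0.025)."""
        q = bs.EventQueue()
        q.push(Event(0.36, 0, 0, 0, 0, 1.0))
        assert q.pop_due(0.350) == []
        out = q.pop_due(0.375)
        assert len(out) == 1

    def test_exact_multiple_boundary_is_not_postponed(self):
        q = bs.EventQueue()
        q.push(Event(15 * 0.025, 0, 0, 0, 0, 1.0))
        assert len(q.pop_due(0.375)) == 1

    def test_pop_order_and_tie_breaking(self):
        q = bs.EventQueue()
        q.push(Event(0.5, 2, 7, 0, 0, 1.0))
        q.push(Event(0.5, 1, 9, 0, 0, 1.0))
        q.push(Event(0.25, 3, 0, 0, 0, 1.0))
        out = q.pop_due(1.0)
        assert [(e.time, e.source) for e in out] == [(0.25, 3), (0.5, 1), (0.5, 2)]


class TestNetworkRun:
    def test_zero_tstop_runs_zero_steps(self):
        net = two_soma_network()
        res = bs.run(net, bs.SimulationClock(tstop=0.0))
        assert res.steps_executed == 0
        assert res.raster == []

    def test_driven_neuron_fires_after_driver_plus_delay(self):
        net = two_soma_network(weight=0.5, delay=1.0)
        res = bs.run(net, bs.SimulationClock(tstop=30.0))
        a = [s.time for s in res.raster if s.source == 0]
        b = [s.time for s in res.raster if s.source == 1]
        assert a and b
        assert min(b) > min(a) + 1.0

    def test_event_conservation(self):
        net = two_soma_network(weight=0.5, delay=1.0)
        res = bs.run(net, bs.SimulationClock(tstop=40.0))
        # every spike of neuron 0 produces exactly one event (out-degree 1)
        n_spikes_a = sum(1 for s in res.raster if s.source == 0)
        assert res.events_emitted == n_spikes_a
        assert res.events_delivered == res.events_emitted

    def test_serial_determinism_bitwise(self):
        r1 = bs.run(two_soma_network(), bs.SimulationClock(tstop=20.0))
        r2 = bs.run(two_soma_network(), bs.SimulationClock(tstop=20.0))
        assert r1.raster_text() == r2.raster_text()
        for nid in r1.traces:
            np.testing.assert_array_equal(r1.traces[nid], r2.traces[nid])

    def test_short_delay_rejected_against_configured_t_synch(self):
        net = two_soma_network(delay=0.05)
        clock = bs.SimulationClock(tstop=1.0, t_synch=0.1)
        with pytest.raises(bs.ConfigurationError):
            bs.run(net, clock)
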