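import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conductsim import (
    AVDelayParams,
    ConductionDelay,
    ConductionParams,
    ModelGraph,
    NEVER,
    OverlapError,
    Pacemaker,
    RefractoryGate,
    SimulationConfig,
    av_delay_duration,
    build_modular_conduction,
    interbeat_samples,
    simulate,
)
from conductsim.conduction import InterbeatTracker

from conftest import brute_refractory_filter, gate_only_model


class TestRefractoryGate:
    def test_first_signal_always_passes(self, config):
        gate = RefractoryGate("g", 1.5)
        state = gate.initial_state(0.0)
        assert state["t_last"] == NEVER
        upd, outs = gate.on_instant(1.0, frozenset({"inp"}), False, state, config)
        assert outs == {"outp"}
        assert upd["t_last"] == 1.0

    def test_filter_sequence(self, config):
        # inputs {1..6}, d_refrac=1.5 -> outputs {1,3,5}
        model = gate_only_model(1.5)
        traces = simulate(model, config, {"model.inp": [1, 2, 3, 4, 5, 6]})
        assert traces["gate.outp"] == (1.0, 3.0, 5.0)
        assert traces["gate.outp"] == brute_refractory_filter([1, 2, 3, 4, 5, 6], 1.5)

    def test_boundary_equality_blocks(self, config):
        # strict inequality: a gap of exactly d_refrac does not pass
        gate = RefractoryGate("g", 1.0)
        state = {"t_last": 0.0}
        upd, outs = gate.on_instant(1.0, frozenset({"inp"}), False, state, config)
        assert outs == frozenset()
        assert upd == {}

    def test_invalid_parameter(self):
        with pytest.raises(ValueError):
            RefractoryGate("g", 0.0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=29.9, allow_nan=False),
            max_size=30,
            unique=True,
        ),
        st.floats(min_value=0.05, max_value=3.0),
    )
    def test_matches_brute_force_oracle(self, times, d_refrac):
        times = sorted(times)
        model = gate_only_model(d_refrac)
        config = SimulationConfig(t_start=0.0, t_stop=30.0)
        traces = simulate(model, config, {"model.inp": times})
        assert traces["gate.outp"] == brute_refractory_filter(times, d_refrac)
        out = traces["gate.outp"]
        assert set(out) <= set(float(t) for t in times)
        assert all(b - a > d_refrac for a, b in zip(out, out[1:]))


def pacemaker_model(period, wire_reset_to_output=False):
    """Pacemaker with boundary inp/reset drive and its output exposed."""
    model = ModelGraph()
    pm = model.add_component(Pacemaker("pm", period))
    inp = model.add_boundary_input("inp")
    outp = model.add_boundary_output("outp")
    model.connect(inp, pm.port("inp"))
    model.connect(pm.port("outp"), outp)
    if wire_reset_to_output:
        model.connect(pm.port("outp"), pm.port("reset"))
    else:
        reset = model.add_boundary_input("reset")
        model.connect(reset, pm.port("reset"))
    return model


class TestPacemaker:
    def test_pass_through_does_not_reset_timer(self, config):
        pm = Pacemaker("pm", 2.0)
        state = {"t_last_reset": 0.0}
        upd, outs = pm.on_instant(1.0, frozenset({"inp"}), False, state, config)
        assert outs == {"outp"}
        assert "t_last_reset" not in upd

    def test_two_inputs_two_outputs(self):
        model = pacemaker_model(5.0)
        config = SimulationConfig(t_start=0.0, t_stop=2.0)
        traces = simulate(model, config, {"model.inp": [0.5, 1.0]})
        assert traces["pm.outp"] == (0.5, 1.0)

    def test_input_at_exact_expiry_dedupes(self):
        # input coinciding with the spontaneous expiry -> one output event
        model = pacemaker_model(2.0)
        config = SimulationConfig(t_start=0.0, t_stop=3.0)
        traces = simulate(model, config, {"model.inp": [2.0]})
        assert traces["pm.outp"].count(2.0) == 1

    def test_reset_postpones_spontaneous(self):
        # resets at {1, 1.8}, period 2 -> no spontaneous output before 3.8
        model = pacemaker_model(2.0)
        config = SimulationConfig(t_start=0.0, t_stop=4.0)
        traces = simulate(model, config, {"model.reset": [1.0, 1.8]})
        assert traces["pm.outp"] == (3.8,)

    def test_spontaneous_sequence(self):
        # no input/reset, period 2, window [0,7] -> outputs {2,4,6}
        model = pacemaker_model(2.0)
        config = SimulationConfig(t_start=0.0, t_stop=7.0)
        traces = simulate(model, config, {})
        assert traces["pm.outp"] == (2.0, 4.0, 6.0)

    def test_reset_then_silence(self):
        model = pacemaker_model(2.0)
        config = SimulationConfig(t_start=0.0, t_stop=3.6)
        traces = simulate(model, config, {"model.reset": [1.5]})
        assert traces["pm.outp"] == (3.5,)

    def test_reset_coinciding_with_expiry_single_output(self):
        model = pacemaker_model(2.0)
        config = SimulationConfig(t_start=0.0, t_stop=4.5)
        traces = simulate(model, config, {"model.reset": [2.0]})
        # single output at 2.0 (spontaneous), next cycle from the reset
        assert traces["pm.outp"] == (2.0, 4.0)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=19.0, allow_nan=False),
            max_size=20,
            unique=True,
        )
    )
    def test_self_reset_bounds_output_gap(self, times):
        # reset wired to own output: maximum output gap <= period (+ tol)
        period = 2.0
        model = pacemaker_model(period, wire_reset_to_output=True)
        config = SimulationConfig(t_start=0.0, t_stop=20.0)
        traces = simulate(model, config, {"model.inp": sorted(times)})
        out = traces["pm.outp"]
        gaps = [b - a for a, b in zip(out, out[1:])]
        assert all(g <= period + 1e-9 for g in gaps)


class TestAVDelayDuration:
    def test_limit_is_d_min(self):
        p = AVDelayParams(0.1, 0.1, 1.0)
        assert av_delay_duration(p, math.inf) == pytest.approx(0.1)

    def test_zero_recovery_is_max(self):
        p = AVDelayParams(0.1, 0.1, 1.0)
        assert av_delay_duration(p, 0.0) == pytest.approx(0.2)

    def test_direct_evaluation(self):
        p = AVDelayParams(0.1, 0.1, 1.0)
        assert av_delay_duration(p, 2.0) == pytest.approx(0.1 + 0.1 * math.exp(-2))

    def test_negative_recovery_rejected(self):
        with pytest.raises(ValueError):
            av_delay_duration(AVDelayParams(0.1, 0.1, 1.0), -0.5)

    @given(st.floats(min_value=0.0, max_value=100.0), st.floats(min_value=0.0, max_value=100.0))
    def test_monotone_non_increasing(self, a, b):
        p = AVDelayParams(0.05, 0.2, 0.7)
        lo, hi = sorted((a, b))
        assert av_delay_duration(p, hi) <= av_delay_duration(p, lo)
        assert av_delay_duration(p, hi) > 0


def delay_only_model(delay_fn):
    model = ModelGraph()
    delay = model.add_component(ConductionDelay("delay", delay_fn))
    inp = model.add_boundary_input("inp")
    outp = model.add_boundary_output("outp")
    model.connect(inp, delay.port("inp"))
    model.connect(delay.port("outp"), outp)
    return model


class TestConductionDelay:
    def test_schedule_from_input(self, config, constant_delay):
        delay = ConductionDelay("d", lambda r: 0.2)
        state = {"pending": False, "t_next": NEVER, "t_last_out": 0.0, "d_delay": 0.0}
        upd, outs = delay.on_instant(2.0, frozenset({"inp"}), False, state, config)
        assert upd["t_next"] == pytest.approx(2.2)
        assert upd["pending"] is True
        assert outs == frozenset()

    def test_per_event_scheduling(self):
        model = delay_only_model(lambda r: 0.2)
        config = SimulationConfig(t_start=0.0, t_stop=4.0)
        traces = simulate(model, config, {"model.inp": [1.0, 2.0, 3.0]})
        assert traces["delay.outp"] == pytest.approx((1.2, 2.2, 3.2))

    def test_overlap_default_drops_with_warning(self, caplog):
        model = delay_only_model(lambda r: 0.2)
        config = SimulationConfig(t_start=0.0, t_stop=1.0, overlap_policy="warn_drop")
        with caplog.at_level("WARNING"):
            traces = simulate(model, config, {"model.inp": [0.1, 0.15]})
        assert traces["delay.outp"] == pytest.approx((0.3,))
        assert any("on hold" in rec.message for rec in caplog.records)

    def test_overlap_policy_error(self):
        model = delay_only_model(lambda r: 0.2)
        config = SimulationConfig(t_start=0.0, t_stop=1.0, overlap_policy="error")
        with pytest.raises(OverlapError):
            simulate(model, config, {"model.inp": [0.1, 0.15]})

    def test_overlap_policy_silent(self, caplog):
        model = delay_only_model(lambda r: 0.2)
        config = SimulationConfig(t_start=0.0, t_stop=1.0, overlap_policy="silent_drop")
        with caplog.at_level("WARNING"):
            traces = simulate(model, config, {"model.inp": [0.1, 0.15]})
        assert traces["delay.outp"] == pytest.approx((0.3,))
        assert not caplog.records

    def test_recovery_measured_from_last_release(self):
        seen = []

        def spy(t_rec):
            seen.append(t_rec)
            return 0.2

        model = delay_only_model(spy)
        config = SimulationConfig(t_start=0.0, t_stop=4.0)
        simulate(model, config, {"model.inp": [1.0, 3.0]})
        # first recovery from NEVER (inf), second from release at 1.2
        assert seen[0] == math.inf
        assert seen[1] == pytest.approx(3.0 - 1.2)

    def test_conserves_event_count_when_spacing_exceeds_delay(self):
        model = delay_only_model(lambda r: 0.3)
        config = SimulationConfig(t_start=0.0, t_stop=20.0)
        times = [0.5 * i for i in range(1, 30)]
        traces = simulate(model, config, {"model.inp": times})
        released = [t for t in times if t + 0.3 <= 20.0]
        assert len(traces["delay.outp"]) == len(released)


class TestInterbeat:
    def test_first_contraction_no_sample(self, config):
        tracker = InterbeatTracker("ib")
        state = tracker.initial_state(0.0)
        upd, _ = tracker.on_instant(2.0, frozenset({"inp"}), False, state, config)
        assert upd["t_last_contraction"] == 2.0
        assert "d_interbeat" not in upd

    def test_sample_is_difference(self, config):
        tracker = InterbeatTracker("ib")
        state = {"t_last_contraction": 2.0, "d_interbeat": math.nan, "samples": ()}
        upd, _ = tracker.on_instant(2.8, frozenset({"inp"}), False, state, config)
        assert upd["d_interbeat"] == pytest.approx(0.8)
        assert upd["samples"] == ((2.8, pytest.approx(0.8)),)

    def test_sequence(self, params, config, constant_delay):
        model = build_modular_conduction(params, delay_fn=constant_delay)
        traces = simulate(model, config, {"model.inp": [0.8, 1.6, 2.4]})
        samples = interbeat_samples(traces)
        assert [d for _, d in samples[:2]] == pytest.approx([0.8, 0.8])


class TestBuildModularConduction:
    def test_structure(self, params):
        model = build_modular_conduction(params)
        assert set(model.components) == {
            "pacemaker",
            "refractoryGate",
            "avConductionDelay",
            "interbeat",
        }
        # reset feedback edge from the gate to the pacemaker
        from conductsim import Port

        assert (Port("refractoryGate", "outp"), Port("pacemaker", "reset")) in (
            model.connections
        )

    def test_boundary_interface(self, params):
        model = build_modular_conduction(params)
        assert [p.name for p in model.boundary_inputs] == ["inp"]
        assert [p.name for p in model.boundary_outputs] == ["outp"]

    def test_interface_variable_counts(self, params):
        model = build_modular_conduction(params)
        assert len(model.components["refractoryGate"].interface) == 2
        assert len(model.components["avConductionDelay"].interface) == 2
        assert len(model.components["pacemaker"].interface) == 3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ConductionParams(d_refrac=-1.0, period=2.0)


class TestConductionDynamics:
    def test_one_to_one_conduction(self, params):
        # d_refrac < T < period -> steady d_interbeat = T
        model = build_modular_conduction(params)
        config = SimulationConfig(t_start=0.0, t_stop=40.0)
        sa = [0.8 * i for i in range(51) if 0.8 * i <= 40.0]
        traces = simulate(model, config, {"model.inp": sa})
        samples = interbeat_samples(traces)
        steady = [d for _, d in samples[10:]]  # recovery transient decays fast
        assert steady == pytest.approx([0.8] * len(steady), abs=1e-9)

    def test_two_to_one_block(self):
        # T < d_refrac <= 2T and 2T < period -> d_interbeat = 2T
        params = ConductionParams(
            d_refrac=0.5, period=2.0, av=AVDelayParams(0.1, 0.1, 1.0)
        )
        model = build_modular_conduction(params)
        config = SimulationConfig(t_start=0.0, t_stop=40.0)
        sa = [0.4 * i for i in range(101) if 0.4 * i <= 40.0]
        traces = simulate(model, config, {"model.inp": sa})
        samples = interbeat_samples(traces)
        steady = [d for _, d in samples[10:]]
        assert steady == pytest.approx([0.8] * len(steady), abs=1e-9)

    def test_escape_converges_to_recovery_fixed_point(self, params):
        # independent oracle: iterate the recovery map f(period - d)
        f = lambda r: av_delay_duration(params.av, r)
        d = f(math.inf)
        for _ in range(200):
            d = f(params.period - d)
        expected_interbeat = params.period  # d_n - d_{n-1} -> 0 at fixpoint

        model = build_modular_conduction(params)
        config = SimulationConfig(t_start=0.0, t_stop=60.0)
        traces = simulate(model, config, {})
        samples = interbeat_samples(traces)
        assert len(samples) >= 20
        t_last, d_last = samples[-1]
        assert d_last == pytest.approx(expected_interbeat, abs=1e-9)
        # the last AV delay itself sits at the fixed point
        assert traces.final_states["avConductionDelay"]["d_delay"] == pytest.approx(
            d, abs=1e-9
        )

    def test_escape_exact_with_constant_delay(self, params, constant_delay):
        model = build_modular_conduction(params, delay_fn=constant_delay)
        config = SimulationConfig(t_start=0.0, t_stop=20.0)
        traces = simulate(model, config, {})
        samples = interbeat_samples(traces)
        # exact from the second beat on
        assert [d for _, d in samples] == pytest.approx(
            [params.period] * len(samples), abs=1e-12
        )
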