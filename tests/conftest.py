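import pytest

from conductsim import (
    AVDelayParams,
    ConductionParams,
    ModelGraph,
    RefractoryGate,
    SimulationConfig,
)


def brute_refractory_filter(times, d_refrac):
    """Independent oracle: pass an event iff the gap to the last passed
    event is strictly greater than d_refrac."""
    out = []
    last = None
    for t in sorted(times):
        if last is None or t - last > d_refrac:
            out.append(t)
            last = t
    return tuple(out)


def gate_only_model(d_refrac):
    """Boundary inp -> RefractoryGate -> boundary outp."""
    model = ModelGraph()
    gate = model.add_component(RefractoryGate("gate", d_refrac))
    inp = model.add_boundary_input("inp")
    outp = model.add_boundary_output("outp")
    model.connect(inp, gate.port("inp"))
    model.connect(gate.port("outp"), outp)
    return model


@pytest.fixture
def params():
    """Explicit parameter set used throughout the tests."""
    return ConductionParams(
        d_refrac=0.3, period=2.0, av=AVDelayParams(d_min=0.1, d_amp=0.1, tau=1.0)
    )


@pytest.fixture
def config():
    return SimulationConfig(t_start=0.0, t_stop=10.0)


@pytest.fixture
def constant_delay():
    return lambda t_rec: 0.1
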