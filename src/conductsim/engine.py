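"""Deterministic discrete-event kernel for zero-delay signal networks.

Signals are instantaneous ("Kronecker delta") events carried on directed
port-to-port connections.  Components react to events and to their own
scheduled timeouts; all consequences of one event instant are resolved
synchronously (zero delay) by fixpoint iteration before time advances.
Handlers see *pre-instant* state only; state writes become visible after
the instant has fully resolved, which makes simultaneous updates
well-defined and order-independent for monotone handlers.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from typing import Optional

#: Sentinel for "has never happened" timestamps.  Using -inf makes
#: ``t - NEVER == +inf``, so first-event conditions pass naturally.
NEVER = float("-inf")

#: Pseudo-component id owning the model boundary ports.
BOUNDARY = "model"

OVERLAP_POLICIES = ("error", "warn_drop", "silent_drop")


class WiringError(ValueError):
    """Raised for causality violations, duplicate or unknown connections."""


class ConvergenceError(RuntimeError):
    """Event-instant fixpoint iteration did not converge (algebraic loop)."""


class OverlapError(RuntimeError):
    """A second signal arrived while one was already on hold."""


@dataclass(frozen=True, order=True)
class Port:
    """A named input or output terminal of a component (or the boundary)."""

    component: str
    name: str

    def __str__(self) -> str:  # used as CSV / DOT identifier
        return f"{self.component}.{self.name}"

    @classmethod
    def parse(cls, text: str) -> "Port":
        component, _, name = text.rpartition(".")
        if not component or not name:
            raise ValueError(f"not a port identifier: {text!r}")
        return cls(component, name)


@dataclass(frozen=True)
class SimulationConfig:
    """Run window, numeric tolerances and policies for :func:`simulate`."""

    t_start: float = 0.0
    t_stop: float = 60.0
    time_tolerance: float = 1e-9
    overlap_policy: str = "warn_drop"
    seed: int = 0
    max_event_iterations: int = 100

    def __post_init__(self) -> None:
        if not self.t_start < self.t_stop:
            raise ValueError("t_start must be < t_stop")
        if not self.time_tolerance > 0:
            raise ValueError("time_tolerance must be > 0")
        if self.overlap_policy not in OVERLAP_POLICIES:
            raise ValueError(f"overlap_policy must be one of {OVERLAP_POLICIES}")


class Component:
    """Base class for event-driven components.

    Subclasses declare their input/output port names and implement
    :meth:`on_instant`.  Handlers must be pure functions of the pre-instant
    state: they return a dict of state updates instead of mutating, and
    they must be monotone in the fired-input set (more inputs at an
    instant may only add fired outputs, never retract them).
    """

    inputs: tuple[str, ...] = ("inp",)
    outputs: tuple[str, ...] = ("outp",)

    def __init__(self, name: str) -> None:
        self.name = name

    def port(self, name: str) -> Port:
        if name not in self.inputs and name not in self.outputs:
            raise WiringError(f"{self.name} has no port {name!r}")
        return Port(self.name, name)

    def initial_state(self, t_start: float) -> dict:
        return {}

    def next_timeout(self, state: Mapping) -> Optional[float]:
        """Earliest pending time-triggered event of this component, if any."""
        return None

    def on_instant(
        self,
        t: float,
        fired_inputs: frozenset,
        timeout_fired: bool,
        state: Mapping,
        config: SimulationConfig,
    ) -> tuple[dict, frozenset]:
        """Handle one event instant; return (state updates, fired outputs)."""
        raise NotImplementedError

    def parameters(self) -> dict:
        """Scalar parameters exposed by this component (for introspection)."""
        return {}

    @property
    def interface(self) -> tuple[str, ...]:
        """Names of the interface variables (connectors) of this component."""
        return self.inputs + self.outputs

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name!r}>"


class ModelGraph:
    """Components plus directed zero-delay connections between ports."""

    def __init__(self) -> None:
        self.components: dict[str, Component] = {}
        self.connections: list[tuple[Port, Port]] = []
        self.boundary_inputs: list[Port] = []
        self.boundary_outputs: list[Port] = []
        self._targets: dict[Port, list[Port]] = defaultdict(list)
        self._has_incoming: set[Port] = set()

    # -- construction -------------------------------------------------

    def add_component(self, component: Component) -> Component:
        if component.name == BOUNDARY:
            raise WiringError(f"component name {BOUNDARY!r} is reserved")
        if component.name in self.components:
            raise WiringError(f"duplicate component name {component.name!r}")
        self.components[component.name] = component
        return component

    def add_boundary_input(self, name: str) -> Port:
        port = Port(BOUNDARY, name)
        if port in self.boundary_inputs or port in self.boundary_outputs:
            raise WiringError(f"duplicate boundary port {name!r}")
        self.boundary_inputs.append(port)
        return port

    def add_boundary_output(self, name: str) -> Port:
        port = Port(BOUNDARY, name)
        if port in self.boundary_inputs or port in self.boundary_outputs:
            raise WiringError(f"duplicate boundary port {name!r}")
        self.boundary_outputs.append(port)
        return port

    # -- port classification ------------------------------------------

    def _is_source(self, port: Port) -> bool:
        """Ports that may emit into the graph: component outputs, boundary inputs."""
        if port.component == BOUNDARY:
            return port in self.boundary_inputs
        comp = self.components.get(port.component)
        return comp is not None and port.name in comp.outputs

    def _is_sink(self, port: Port) -> bool:
        """Ports that may receive: component inputs, boundary outputs."""
        if port.component == BOUNDARY:
            return port in self.boundary_outputs
        comp = self.components.get(port.component)
        return comp is not None and port.name in comp.inputs

    def _known(self, port: Port) -> bool:
        if port.component == BOUNDARY:
            return port in self.boundary_inputs or port in self.boundary_outputs
        comp = self.components.get(port.component)
        return comp is not None and (
            port.name in comp.inputs or port.name in comp.outputs
        )

    def all_ports(self) -> list[Port]:
        ports = list(self.boundary_inputs) + list(self.boundary_outputs)
        for comp in self.components.values():
            ports.extend(Port(comp.name, n) for n in comp.interface)
        return ports

    # -- wiring -------------------------------------------------------

    def connect(self, source: Port, target: Port) -> "ModelGraph":
        if not self._known(source):
            raise WiringError(f"unknown port {source}")
        if not self._known(target):
            raise WiringError(f"unknown port {target}")
        if not self._is_source(source) or not self._is_sink(target):
            raise WiringError(f"causality violation: {source} -> {target}")
        if (source, target) in self.connections:
            raise WiringError(f"duplicate connection {source} -> {target}")
        if target in self._has_incoming:
            raise WiringError(
                f"{target} already has an incoming connection; "
                "route fan-in through an explicit logic gate"
            )
        self.connections.append((source, target))
        self._targets[source].append(target)
        self._has_incoming.add(target)
        return self


def connect(model: ModelGraph, source: Port, target: Port) -> ModelGraph:
    """Add a directed output-to-input connection to *model* (and return it)."""
    return model.connect(source, target)


class TraceSet(Mapping):
    """Mapping ``Port -> tuple of event times`` for every port in a model.

    String keys of the form ``"component.port"`` are accepted as well.
    Carries the components' final discrete states in :attr:`final_states`.
    """

    def __init__(self, data: Mapping, final_states: Optional[Mapping] = None):
        self._data = {self._key(p): tuple(ts) for p, ts in data.items()}
        self.final_states: dict = {k: dict(v) for k, v in (final_states or {}).items()}

    @staticmethod
    def _key(key) -> Port:
        return Port.parse(key) if isinstance(key, str) else key

    def __getitem__(self, key) -> tuple:
        return self._data[self._key(key)]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def ports(self) -> list[Port]:
        return sorted(self._data)

    def __eq__(self, other) -> bool:
        if isinstance(other, TraceSet):
            return self._data == other._data
        return NotImplemented


# ---------------------------------------------------------------------
# Event resolution
# ---------------------------------------------------------------------


def initial_states(model: ModelGraph, t_start: float) -> dict:
    """Fresh per-component state dicts for a run starting at *t_start*."""
    return {
        cid: dict(comp.initial_state(t_start))
        for cid, comp in model.components.items()
    }


def next_timeout(model: ModelGraph, states: Mapping) -> Optional[tuple[float, str]]:
    """Earliest pending component timeout as ``(time, component_id)``.

    Ties break on component id so the result is deterministic.
    """
    best: Optional[tuple[float, str]] = None
    for cid in sorted(model.components):
        t = model.components[cid].next_timeout(states[cid])
        if t is None or math.isinf(t):
            continue
        if best is None or (t, cid) < best:
            best = (t, cid)
    return best


def resolve_instant(
    model: ModelGraph,
    states: Mapping,
    t: float,
    initial_emissions,
    config: SimulationConfig,
    timeouts=(),
) -> tuple[set, dict]:
    """Resolve all zero-delay consequences of one event instant.

    *initial_emissions* are ports already firing at ``t`` (boundary inputs
    carrying external stimuli and/or component outputs); *timeouts* names
    components whose scheduled timeout expires at ``t``.  Returns the set
    of all fired ports and the post-instant states.  Each output fires at
    most once per instant and every handler is evaluated against
    pre-instant state.
    """
    fired, _, new_states = _resolve(model, states, t, initial_emissions, timeouts, config)
    return fired, new_states


def _resolve(model, states, t, seeds, timeout_comps, config):
    timeout_comps = set(timeout_comps)
    fired: set[Port] = set()
    delivered: set[Port] = set()
    fired_inputs: dict[str, set[str]] = defaultdict(set)
    evaluated_with: dict[str, tuple[frozenset, bool]] = {}
    updates: dict[str, dict] = {}

    def deliver(port: Port) -> bool:
        if port in fired:
            return False
        fired.add(port)
        for tgt in model._targets.get(port, ()):
            delivered.add(tgt)
            if tgt.component != BOUNDARY:
                fired_inputs[tgt.component].add(tgt.name)
        return True

    for port in sorted(set(seeds)):
        deliver(port)

    order = list(model.components)
    max_iter = max(config.max_event_iterations, len(order) + 2)
    for _ in range(max_iter):
        progressed = False
        for cid in order:
            has_timeout = cid in timeout_comps
            inputs_now = frozenset(fired_inputs.get(cid, ()))
            if not has_timeout and not inputs_now:
                continue
            if evaluated_with.get(cid) == (inputs_now, has_timeout):
                continue
            comp = model.components[cid]
            upd, outs = comp.on_instant(t, inputs_now, has_timeout, states[cid], config)
            evaluated_with[cid] = (inputs_now, has_timeout)
            updates[cid] = dict(upd)
            progressed = True
            for out_name in sorted(outs):
                deliver(Port(cid, out_name))
        if not progressed:
            break
    else:
        raise ConvergenceError(
            f"event instant at t={t} did not converge within {max_iter} iterations"
        )

    new_states = {
        cid: ({**states[cid], **updates[cid]} if cid in updates else states[cid])
        for cid in model.components
    }
    return fired, delivered, new_states


# ---------------------------------------------------------------------
# Simulation loop
# ---------------------------------------------------------------------


def _normalize_external(model: ModelGraph, external, config) -> dict[Port, list[float]]:
    ext: dict[Port, list[float]] = {}
    for key, times in (external or {}).items():
        port = Port.parse(key) if isinstance(key, str) else key
        if port.component != BOUNDARY and port.component == "":
            port = Port(BOUNDARY, port.name)
        if port not in model.boundary_inputs:
            raise WiringError(f"{port} is not a boundary input of the model")
        times = [float(x) for x in times]
        for a, b in zip(times, times[1:]):
            if not b > a:
                raise ValueError(f"external trace for {port} not strictly increasing")
        for x in times:
            if x < config.t_start or x > config.t_stop:
                raise ValueError(
                    f"external event {x} outside [{config.t_start}, {config.t_stop}]"
                )
        ext[port] = times
    return ext


def simulate(
    model: ModelGraph,
    config: SimulationConfig,
    external: Optional[Mapping] = None,
) -> TraceSet:
    """Run *model* over ``[t_start, t_stop]`` driven by external traces.

    External events and expired timeouts closer together than
    ``time_tolerance`` are merged into a single instant.  The result is a
    pure function of (model, config, external): identical arguments yield
    a bit-identical :class:`TraceSet`.
    """
    states = initial_states(model, config.t_start)
    ext = _normalize_external(model, external, config)
    idx = {port: 0 for port in ext}
    traces: dict[Port, list[float]] = {p: [] for p in model.all_ports()}

    tol = config.time_tolerance
    t_prev: Optional[float] = None
    while True:
        candidates = [
            times[idx[port]] for port, times in ext.items() if idx[port] < len(times)
        ]
        pending = next_timeout(model, states)
        if pending is not None:
            candidates.append(pending[0])
        if not candidates:
            break
        t = min(candidates)
        if t > config.t_stop:
            break
        if t_prev is not None and t <= t_prev:
            raise RuntimeError(f"time did not advance at t={t}")

        seeds = set()
        for port in sorted(ext):
            times = ext[port]
            while idx[port] < len(times) and times[idx[port]] <= t + tol:
                seeds.add(port)
                idx[port] += 1
        timeout_comps = {
            cid
            for cid, comp in model.components.items()
            if (to := comp.next_timeout(states[cid])) is not None and to <= t + tol
        }

        fired, delivered, states = _resolve(model, states, t, seeds, timeout_comps, config)
        for port in fired | delivered:
            traces[port].append(t)
        t_prev = t

    return TraceSet(traces, final_states=states)
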