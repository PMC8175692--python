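"""Premature-ventricular-contraction (PVC) extension of the conduction model.

Adds stateless OR/AND logic gates, a second refractory gate for the
ventricles, and a boundary trigger input ``pvc``.  Behavioral contract:

* a PVC trigger during the ventricular refractory period produces no
  ventricular event;
* a trigger outside it produces an immediate ventricular event;
* every ventricular event -- conducted or ectopic -- starts a ventricular
  refractory period that also blocks conducted beats.
"""

from __future__ import annotations

from .conduction import (
    AVConductionDelay,
    ConductionDelay,
    ConductionParams,
    InterbeatTracker,
    Pacemaker,
    RefractoryGate,
)
from .engine import Component, ModelGraph
from dataclasses import dataclass
from typing import Callable, Optional


class OrGate(Component):
    """Fires its output iff at least one input fires at the instant;
    simultaneous input firings merge into a single output event."""

    outputs = ("outp",)

    def __init__(self, name: str, arity: int = 2) -> None:
        super().__init__(name)
        if arity < 2:
            raise ValueError("gate arity must be >= 2")
        self.arity = arity
        self.inputs = tuple(f"in{i + 1}" for i in range(arity))

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        if fired_inputs:
            return {}, frozenset({"outp"})
        return {}, frozenset()


class AndGate(Component):
    """Fires iff *all* inputs fire at the same resolved instant."""

    outputs = ("outp",)

    def __init__(self, name: str, arity: int = 2) -> None:
        super().__init__(name)
        if arity < 2:
            raise ValueError("gate arity must be >= 2")
        self.arity = arity
        self.inputs = tuple(f"in{i + 1}" for i in range(arity))

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        if len(fired_inputs) == self.arity:
            return {}, frozenset({"outp"})
        return {}, frozenset()


def or_gate_fire(inputs_fired) -> bool:
    """OR semantics at one resolved instant."""
    return len(set(inputs_fired)) >= 1


def and_gate_fire(inputs_fired, arity: int) -> bool:
    """AND semantics at one resolved instant."""
    return len(set(inputs_fired)) == arity


@dataclass(frozen=True)
class PVCModelParams:
    base: ConductionParams = ConductionParams()
    d_refrac_ventricle: float = 0.25

    def __post_init__(self) -> None:
        if not self.d_refrac_ventricle > 0:
            raise ValueError("d_refrac_ventricle must be > 0")


def build_pvc_conduction(
    params: PVCModelParams,
    delay_fn: Optional[Callable[[float], float]] = None,
) -> ModelGraph:
    """Extend the modular conduction model with a PVC trigger.

    Wiring (two OR gates, one AND gate, second refractory gate):

    * ``orVentricle`` merges the conducted stream (AV delay output) with
      the external ``pvc`` trigger and drives ``ventricularGate``, whose
      output is the ventricular boundary output -- so every emitted beat
      opens a ventricular refractory window blocking later triggers and
      conducted beats alike;
    * ``andPvc`` detects a *conducted* PVC (trigger and ventricular event
      at the same instant) and ``orReset`` merges it with the SA-side gate
      output into the pacemaker reset, so an ectopic beat that captured
      the ventricles also restarts the escape timer.
    """
    base = params.base
    model = ModelGraph()
    pacemaker = model.add_component(Pacemaker("pacemaker", base.period))
    sa_gate = model.add_component(RefractoryGate("refractoryGate", base.d_refrac))
    if delay_fn is None:
        delay = model.add_component(AVConductionDelay("avConductionDelay", base.av))
    else:
        delay = model.add_component(ConductionDelay("avConductionDelay", delay_fn))
    or_vent = model.add_component(OrGate("orVentricle"))
    vent_gate = model.add_component(
        RefractoryGate("ventricularGate", params.d_refrac_ventricle)
    )
    and_pvc = model.add_component(AndGate("andPvc"))
    or_reset = model.add_component(OrGate("orReset"))
    interbeat = model.add_component(InterbeatTracker("interbeat"))

    inp = model.add_boundary_input("inp")
    pvc = model.add_boundary_input("pvc")
    outp = model.add_boundary_output("outp")

    model.connect(inp, pacemaker.port("inp"))
    model.connect(pacemaker.port("outp"), sa_gate.port("inp"))
    model.connect(sa_gate.port("outp"), delay.port("inp"))
    model.connect(delay.port("outp"), or_vent.port("in1"))
    model.connect(pvc, or_vent.port("in2"))
    model.connect(or_vent.port("outp"), vent_gate.port("inp"))
    model.connect(vent_gate.port("outp"), outp)
    model.connect(vent_gate.port("outp"), interbeat.port("inp"))
    model.connect(pvc, and_pvc.port("in1"))
    model.connect(vent_gate.port("outp"), and_pvc.port("in2"))
    model.connect(sa_gate.port("outp"), or_reset.port("in1"))
    model.connect(and_pvc.port("outp"), or_reset.port("in2"))
    model.connect(or_reset.port("outp"), pacemaker.port("reset"))
    return model
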