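"""Physiological components and the modular cardiac conduction model.

Three reusable event components form a pipeline from the sinoatrial (SA)
input to the ventricular output:

* :class:`RefractoryGate` -- drops events arriving within the refractory
  period after the last event that passed;
* :class:`Pacemaker` -- passes events through and additionally fires on
  its own when its timer has not been reset for one period (AV-nodal
  escape); the timer reset is a *separate* input so that blocked signals
  do not prematurely reset it;
* :class:`ConductionDelay` / :class:`AVConductionDelay` -- holds each
  event and releases it after a delay that depends on the recovery time
  since the last released event.

:func:`build_modular_conduction` wires them up (with the reset feedback
edge from the gate back to the pacemaker) and attaches an interbeat
tracker to the ventricular output.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Callable, Optional

from .engine import (
    NEVER,
    Component,
    ModelGraph,
    OverlapError,
    SimulationConfig,
)

log = logging.getLogger(__name__)

DelayFn = Callable[[float], float]


# ---------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class AVDelayParams:
    """Recovery-curve parameters of the AV conduction delay (seconds).

    The delay for an event arriving ``t_rec`` seconds after the previous
    released event is ``d_min + d_amp * exp(-t_rec / tau)``.
    """

    d_min: float = 0.1
    d_amp: float = 0.13
    tau: float = 0.8

    def __post_init__(self) -> None:
        if not self.d_min > 0:
            raise ValueError("d_min must be > 0")
        if self.d_amp < 0:
            raise ValueError("d_amp must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")


def av_delay_duration(params: AVDelayParams, t_rec: float) -> float:
    """Recovery-dependent AV delay: ``d_min + d_amp * exp(-t_rec/tau)``.

    Strictly positive and monotone non-increasing in the recovery time
    ``t_rec``; ``t_rec = +inf`` (no previous output) gives ``d_min``.
    """
    if t_rec < 0:
        raise ValueError(f"recovery time must be >= 0, got {t_rec}")
    return params.d_min + params.d_amp * math.exp(-t_rec / params.tau)


@dataclass(frozen=True)
class ConductionParams:
    """The five scalar parameters of the conduction model.

    Default values are plausible placeholders for a resting human heart
    (SA-node refractory period, AV escape period, AV recovery curve);
    experiments should set them explicitly.
    """

    d_refrac: float = 0.35
    period: float = 1.7
    av: AVDelayParams = AVDelayParams()

    def __post_init__(self) -> None:
        if not self.d_refrac > 0:
            raise ValueError("d_refrac must be > 0")
        if not self.period > 0:
            raise ValueError("period must be > 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConductionParams":
        """Build from config keys ``d_refrac_s``, ``period_s``, ``av.*_s``."""
        av_data = data.get("av", {})
        av = AVDelayParams(
            d_min=float(av_data.get("d_min_s", AVDelayParams.d_min)),
            d_amp=float(av_data.get("d_amp_s", AVDelayParams.d_amp)),
            tau=float(av_data.get("tau_s", AVDelayParams.tau)),
        )
        return cls(
            d_refrac=float(data.get("d_refrac_s", cls.d_refrac)),
            period=float(data.get("period_s", cls.period)),
            av=av,
        )

    def to_dict(self) -> dict:
        return {
            "d_refrac_s": self.d_refrac,
            "period_s": self.period,
            "av": {
                "d_min_s": self.av.d_min,
                "d_amp_s": self.av.d_amp,
                "tau_s": self.av.tau,
            },
        }

    def scalars(self) -> dict:
        """Flat view of all scalar parameters."""
        return {
            "d_refrac_s": self.d_refrac,
            "period_s": self.period,
            "d_min_s": self.av.d_min,
            "d_amp_s": self.av.d_amp,
            "tau_s": self.av.tau,
        }


# ---------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------


class RefractoryGate(Component):
    """Passes an event iff strictly more than ``d_refrac`` has elapsed
    since the last event that passed; boundary equality blocks."""

    inputs = ("inp",)
    outputs = ("outp",)

    def __init__(self, name: str, d_refrac: float) -> None:
        super().__init__(name)
        if not d_refrac > 0:
            raise ValueError("d_refrac must be > 0")
        self.d_refrac = d_refrac

    def initial_state(self, t_start: float) -> dict:
        return {"t_last": NEVER}

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        if "inp" in fired_inputs and t - state["t_last"] > self.d_refrac:
            return {"t_last": t}, frozenset({"outp"})
        return {}, frozenset()

    def parameters(self) -> dict:
        return {"d_refrac_s": self.d_refrac}


class Pacemaker(Component):
    """Pass-through that fires spontaneously when its timer expires.

    The timer is reset by the dedicated ``reset`` input or by a
    spontaneous firing -- *not* by a pass-through, so that signals
    blocked downstream cannot silently restart the escape countdown.
    """

    inputs = ("inp", "reset")
    outputs = ("outp",)

    def __init__(self, name: str, period: float) -> None:
        super().__init__(name)
        if not period > 0:
            raise ValueError("period must be > 0")
        self.period = period

    def initial_state(self, t_start: float) -> dict:
        return {"t_last_reset": t_start}

    def next_timeout(self, state) -> Optional[float]:
        return state["t_last_reset"] + self.period

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        updates: dict = {}
        outs: frozenset = frozenset()
        if timeout_fired or "inp" in fired_inputs:
            outs = frozenset({"outp"})
        if timeout_fired or "reset" in fired_inputs:
            updates["t_last_reset"] = t
        return updates, outs

    def parameters(self) -> dict:
        return {"period_s": self.period}


class ConductionDelay(Component):
    """Holds each incoming event and re-emits it after ``delay_fn(t_rec)``
    where ``t_rec`` is the time since the last emitted event.

    At most one event can be on hold; a second input while holding
    violates the model's single-hold assumption and is handled according
    to ``config.overlap_policy`` (error / warn_drop / silent_drop).
    """

    inputs = ("inp",)
    outputs = ("outp",)

    def __init__(self, name: str, delay_fn: DelayFn) -> None:
        super().__init__(name)
        self.delay_fn = delay_fn

    def initial_state(self, t_start: float) -> dict:
        return {
            "pending": False,
            "t_next": NEVER,
            "t_last_out": NEVER,
            "d_delay": math.nan,
        }

    def next_timeout(self, state) -> Optional[float]:
        return state["t_next"] if state["pending"] else None

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        updates: dict = {}
        outs: frozenset = frozenset()
        pending = state["pending"]
        t_last_out = state["t_last_out"]

        if timeout_fired:  # release the held event
            outs = frozenset({"outp"})
            updates["t_last_out"] = t
            updates["pending"] = False
            pending = False
            t_last_out = t

        if "inp" in fired_inputs:
            if pending:
                self._overlap(t, state, config)
            else:
                d = self.delay_fn(t - t_last_out)
                if not d > 0:
                    raise ValueError(f"delay_fn returned non-positive delay {d}")
                updates["d_delay"] = d
                updates["t_next"] = t + d
                updates["pending"] = True
        return updates, outs

    def _overlap(self, t: float, state, config: SimulationConfig) -> None:
        msg = (
            f"{self.name}: input at t={t} while a signal is on hold "
            f"until t={state['t_next']}; dropping it"
        )
        if config.overlap_policy == "error":
            raise OverlapError(msg)
        if config.overlap_policy == "warn_drop":
            log.warning(msg)


class AVConductionDelay(ConductionDelay):
    """Conduction delay with the AV-node exponential recovery curve."""

    def __init__(self, name: str, params: AVDelayParams) -> None:
        self.params = params
        super().__init__(name, lambda t_rec: av_delay_duration(params, t_rec))

    def parameters(self) -> dict:
        return {
            "d_min_s": self.params.d_min,
            "d_amp_s": self.params.d_amp,
            "tau_s": self.params.tau,
        }


class InterbeatTracker(Component):
    """Observer that records contraction times and interbeat intervals.

    Readouts live in its discrete state: ``t_last_contraction``,
    ``d_interbeat`` (defined from the second contraction on) and the full
    ``samples`` tuple of ``(time, interval)`` pairs.
    """

    inputs = ("inp",)
    outputs = ()

    def initial_state(self, t_start: float) -> dict:
        return {"t_last_contraction": NEVER, "d_interbeat": math.nan, "samples": ()}

    def on_instant(self, t, fired_inputs, timeout_fired, state, config):
        if "inp" not in fired_inputs:
            return {}, frozenset()
        updates = {"t_last_contraction": t}
        if state["t_last_contraction"] != NEVER:
            d = t - state["t_last_contraction"]
            updates["d_interbeat"] = d
            updates["samples"] = state["samples"] + ((t, d),)
        return updates, frozenset()


# ---------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------

#: The three physiological component classes of the modular model.
PHYSIOLOGICAL_COMPONENTS = (Pacemaker, RefractoryGate, AVConductionDelay)


def build_modular_conduction(
    params: ConductionParams,
    delay_fn: Optional[DelayFn] = None,
) -> ModelGraph:
    """Assemble the modular conduction model.

    Wiring: boundary ``inp`` -> pacemaker -> refractory gate -> AV delay
    -> boundary ``outp``; the gate output additionally feeds back into the
    pacemaker's reset, so only signals that survived the refractory check
    restart the escape timer.  An :class:`InterbeatTracker` listens on the
    ventricular output.

    *delay_fn* substitutes an arbitrary recovery->delay map for the
    default AV exponential (useful for constant-delay experiments).
    """
    model = ModelGraph()
    pacemaker = model.add_component(Pacemaker("pacemaker", params.period))
    gate = model.add_component(RefractoryGate("refractoryGate", params.d_refrac))
    if delay_fn is None:
        delay = model.add_component(AVConductionDelay("avConductionDelay", params.av))
    else:
        delay = model.add_component(ConductionDelay("avConductionDelay", delay_fn))
    interbeat = model.add_component(InterbeatTracker("interbeat"))

    inp = model.add_boundary_input("inp")
    outp = model.add_boundary_output("outp")

    model.connect(inp, pacemaker.port("inp"))
    model.connect(pacemaker.port("outp"), gate.port("inp"))
    model.connect(gate.port("outp"), delay.port("inp"))
    model.connect(gate.port("outp"), pacemaker.port("reset"))
    model.connect(delay.port("outp"), outp)
    model.connect(delay.port("outp"), interbeat.port("inp"))
    return model


def interbeat_samples(traces) -> tuple:
    """``(time, interval)`` samples recorded online by the interbeat tracker."""
    return traces.final_states["interbeat"]["samples"]
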