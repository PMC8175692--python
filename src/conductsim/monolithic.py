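"""Scheduling-based monolithic reference implementation.

Reconstructs the original single-block design of the conduction system:
instead of propagating actual signals, a scheduler keeps track of the next
time a contraction will be issued, giving precedence to candidates that
enter the schedule later but would take effect earlier.  Used as an
equivalence oracle for the modular model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .conduction import ConductionParams, av_delay_duration
from .engine import NEVER, SimulationConfig


class MonolithicConduction:
    """Event loop over SA signals and one scheduled contraction time.

    On an SA signal at ``t``: if more than ``d_refrac`` has elapsed since
    the last *accepted* signal (refractory checked before the delay), the
    signal is accepted and proposes a contraction at
    ``t + delay(t - t_last_contraction)``; the proposal wins if it is
    earlier than the current schedule.  Each contraction re-arms the
    escape fallback at ``t_c + period``.
    """

    def __init__(
        self,
        params: ConductionParams,
        delay_fn: Optional[Callable[[float], float]] = None,
    ) -> None:
        self.params = params
        self.delay_fn = delay_fn or (
            lambda t_rec: av_delay_duration(params.av, t_rec)
        )

    def parameters(self) -> dict:
        """All scalar parameters of the monolithic block (five)."""
        return self.params.scalars()

    def simulate(
        self, sa: Sequence[float], config: SimulationConfig
    ) -> tuple[tuple, tuple]:
        """Return ``(v_trace, interbeat_series)`` for the SA event trace."""
        sa = tuple(float(t) for t in sa)
        for a, b in zip(sa, sa[1:]):
            if not b > a:
                raise ValueError("SA trace must be strictly increasing")

        d_refrac = self.params.d_refrac
        period = self.params.period
        f = self.delay_fn

        t_last_accept = NEVER
        t_last_contraction = NEVER
        # Initial escape schedule mirrors the modular model's first
        # spontaneous beat: timer from t_start plus the fully recovered delay.
        t_sched = config.t_start + period + f(math.inf)
        v: list[float] = []
        interbeat: list[tuple[float, float]] = []

        i = 0
        while True:
            t_sa = sa[i] if i < len(sa) else None
            fire_sched = t_sched <= config.t_stop and (
                t_sa is None or t_sched <= t_sa
            )
            if fire_sched:
                t_c = t_sched
                v.append(t_c)
                if t_last_contraction != NEVER:
                    interbeat.append((t_c, t_c - t_last_contraction))
                t_last_contraction = t_c
                t_sched = t_c + period
                continue
            if t_sa is None or t_sa > config.t_stop:
                break
            i += 1
            if t_sa - t_last_accept > d_refrac:
                t_last_accept = t_sa
                candidate = t_sa + f(t_sa - t_last_contraction)
                # later-entering but earlier-acting proposals take precedence
                if candidate < t_sched:
                    t_sched = candidate
        return tuple(v), tuple(interbeat)


def monolithic_simulate(
    params: ConductionParams,
    sa: Sequence[float],
    config: SimulationConfig,
    delay_fn: Optional[Callable[[float], float]] = None,
) -> tuple[tuple, tuple]:
    """Functional front end for :class:`MonolithicConduction`."""
    return MonolithicConduction(params, delay_fn).simulate(sa, config)


# ---------------------------------------------------------------------
# Interbeat-series comparison
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonReport:
    """Alignment of two interbeat series.

    ``divergences`` lists ``(time, delta)`` pairs: time-matched samples
    whose intervals differ by more than the tolerance (delta is the
    absolute interval difference) and unmatched samples present in only
    one series (delta is ``nan``).
    """

    n_matched: int
    max_abs_diff: float
    divergences: tuple = field(default_factory=tuple)

    @property
    def n_divergent(self) -> int:
        return len(self.divergences)


def compare_interbeat(a, b, tol: float) -> ComparisonReport:
    """Compare two ``(time, interval)`` series sample by sample.

    Samples are paired when their timestamps agree within *tol*; paired
    samples diverge when their intervals differ by more than *tol*.
    """
    a = sorted(a)
    b = sorted(b)
    i = j = 0
    n_matched = 0
    max_diff = 0.0
    divergences: list[tuple[float, float]] = []
    while i < len(a) and j < len(b):
        ta, da = a[i]
        tb, db = b[j]
        if abs(ta - tb) <= tol:
            diff = abs(da - db)
            n_matched += 1
            max_diff = max(max_diff, diff)
            if diff > tol:
                divergences.append((ta, diff))
            i += 1
            j += 1
        elif ta < tb:
            divergences.append((ta, math.nan))
            i += 1
        else:
            divergences.append((tb, math.nan))
            j += 1
    for ta, _ in a[i:]:
        divergences.append((ta, math.nan))
    for tb, _ in b[j:]:
        divergences.append((tb, math.nan))
    divergences.sort(key=lambda p: p[0])
    return ComparisonReport(n_matched, max_diff, tuple(divergences))
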