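"""Stimulus generation, interbeat analysis, CSV I/O and experiment runs.

The stimulus module emulates the bench protocol used to exercise the
model: a periodic SA signal whose inter-stimulus interval switches to a
new value every 5-10 seconds.
"""

from __future__ import annotations

import csv
import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .conduction import (
    ConductionParams,
    build_modular_conduction,
    interbeat_samples,
)
from .engine import Port, SimulationConfig, TraceSet, simulate
from .monolithic import ComparisonReport, compare_interbeat, monolithic_simulate
from .pvc import PVCModelParams, build_pvc_conduction

FLOAT_FMT = ".9g"


# ---------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant SA inter-stimulus interval schedule.

    ``segments`` is an ordered list of ``(t_switch, interval)``; the first
    switch time must equal ``t_start`` and each interval is in force from
    its switch time until the next one.
    """

    segments: tuple
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        segments = tuple((float(t), float(d)) for t, d in self.segments)
        object.__setattr__(self, "segments", segments)
        if not segments:
            raise ValueError("protocol needs at least one segment")
        if segments[0][0] != self.t_start:
            raise ValueError("first switch time must equal t_start")
        for (t0, _), (t1, _) in zip(segments, segments[1:]):
            if not t1 > t0:
                raise ValueError("switch times must be strictly increasing")
        for _, interval in segments:
            if not interval > 0:
                raise ValueError("intervals must be > 0")
        if self.t_stop < self.t_start:
            raise ValueError("t_stop must be >= t_start")

    def interval_at(self, t: float) -> float:
        """Interval in force at time ``t`` (last switch at or before ``t``)."""
        current = self.segments[0][1]
        for t_switch, interval in self.segments:
            if t_switch <= t:
                current = interval
            else:
                break
        return current


def generate_sa_stimulus(protocol: StimulusProtocol) -> tuple:
    """Expand a protocol into an SA event trace.

    The first event is at ``t_start``; each next event follows the
    previous one by the interval in force *at the previous event's time*.
    Events run up to and including ``t_stop``.
    """
    times = [protocol.t_start]
    while True:
        nxt = times[-1] + protocol.interval_at(times[-1])
        if nxt > protocol.t_stop:
            break
        times.append(nxt)
    return tuple(times)


def sample_switching_protocol(
    seed: int,
    t_start: float,
    t_stop: float,
    interval_choices: Sequence[float],
    switch_gap_range: tuple = (5.0, 10.0),
) -> StimulusProtocol:
    """Random protocol whose interval switches every 5-10 s (seeded)."""
    choices = [float(x) for x in interval_choices]
    if not choices:
        raise ValueError("interval_choices must be nonempty")
    lo, hi = switch_gap_range
    rng = np.random.default_rng(seed)
    segments = []
    t = float(t_start)
    while t < t_stop or not segments:
        segments.append((t, choices[int(rng.integers(len(choices)))]))
        t += float(rng.uniform(lo, hi))
    return StimulusProtocol(tuple(segments), float(t_start), float(t_stop))


# ---------------------------------------------------------------------
# Interbeat analysis
# ---------------------------------------------------------------------


def extract_interbeat(v: Sequence[float]) -> tuple:
    """``(t_i, t_i - t_{i-1})`` samples from a contraction trace."""
    v = tuple(v)
    return tuple((b, b - a) for a, b in zip(v, v[1:]))


def conduction_ratio(
    sa: Sequence[float], v: Sequence[float], window: tuple
) -> Optional[tuple]:
    """Reduced SA:V event-count ratio within ``window`` (inclusive).

    Returns ``None`` when the window contains no ventricular events.
    """
    lo, hi = window
    n_sa = sum(1 for t in sa if lo <= t <= hi)
    n_v = sum(1 for t in v if lo <= t <= hi)
    if n_v == 0:
        return None
    g = math.gcd(n_sa, n_v)
    return (n_sa // g, n_v // g)


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(x, FLOAT_FMT)


def write_trace_csv(traces: Mapping, path) -> None:
    """Write a port->trace mapping as ``time_s,port`` rows.

    Rows are sorted by (time, port name); floats use ``%.9g``; UTF-8, LF.
    """
    rows = []
    for port, times in traces.items():
        name = str(port)
        rows.extend((t, name) for t in times)
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_s", "port"])
        for t, name in rows:
            writer.writerow([_fmt(t), name])


def read_trace_csv(path) -> dict:
    """Read a trace CSV back into ``{port_id: tuple of times}``.

    Rejects files whose per-port times are not strictly increasing.
    """
    traces: dict[str, list[float]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["time_s", "port"]:
            raise ValueError(f"malformed trace CSV header: {header}")
        for row in reader:
            if len(row) != 2:
                raise ValueError(f"malformed trace CSV row: {row}")
            t, port = float(row[0]), row[1]
            bucket = traces.setdefault(port, [])
            if bucket and t <= bucket[-1]:
                raise ValueError(f"non-monotone times for port {port!r}")
            bucket.append(t)
    return {port: tuple(ts) for port, ts in traces.items()}


def write_interbeat_csv(series, path) -> None:
    """Write ``(time, interval)`` samples as ``time_s,d_interbeat_s`` rows."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_s", "d_interbeat_s"])
        for t, d in series:
            writer.writerow([_fmt(t), _fmt(d)])


# ---------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------


@dataclass
class ExperimentResult:
    traces: TraceSet
    interbeat: tuple
    config: dict
    provenance: dict
    comparison: Optional[ComparisonReport] = None


def load_config(path) -> dict:
    """Load an experiment config from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _build_stimulus(cfg: dict, t_start: float, t_stop: float, seed: int):
    stim = cfg.get("stimulus", {"kind": "none"})
    kind = stim.get("kind", "constant")
    if kind == "none":
        return ()
    if kind == "constant":
        protocol = StimulusProtocol(
            ((t_start, float(stim["interval_s"])),), t_start, t_stop
        )
        return generate_sa_stimulus(protocol)
    if kind == "switching":
        protocol = sample_switching_protocol(
            seed=stim.get("seed", seed),
            t_start=t_start,
            t_stop=t_stop,
            interval_choices=stim["choices_s"],
            switch_gap_range=tuple(stim.get("switch_gap_range_s", (5.0, 10.0))),
        )
        return generate_sa_stimulus(protocol)
    if kind == "trace":
        traces = read_trace_csv(stim["path"])
        return traces[stim.get("port", "model.inp")]
    raise ValueError(f"unknown stimulus kind {kind!r}")


def run_experiment(config, out_dir=None) -> ExperimentResult:
    """Run a configured simulation and (optionally) write its artifacts.

    *config* is a dict or a YAML/JSON path.  Writes ``traces.csv``,
    ``interbeat.csv`` and ``provenance.json`` into *out_dir*; in compare
    mode additionally ``interbeat_monolithic.csv`` and ``comparison.json``.
    All outputs are byte-reproducible from (config, seed).
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    cfg = dict(config)

    model_kind = cfg.get("model", "modular")
    seed = int(cfg.get("seed", 0))
    t_start = float(cfg.get("t_start", 0.0))
    t_stop = float(cfg.get("t_stop", 60.0))
    params = ConductionParams.from_dict(cfg.get("params", {}))
    sim_config = SimulationConfig(
        t_start=t_start,
        t_stop=t_stop,
        time_tolerance=float(cfg.get("time_tolerance_s", 1e-9)),
        overlap_policy=cfg.get("overlap_policy", "warn_drop"),
        seed=seed,
    )
    sa = _build_stimulus(cfg, t_start, t_stop, seed)

    comparison = None
    if model_kind == "modular":
        model = build_modular_conduction(params)
        traces = simulate(model, sim_config, {"model.inp": sa})
        interbeat = interbeat_samples(traces)
    elif model_kind == "pvc":
        pvc_params = PVCModelParams(
            base=params,
            d_refrac_ventricle=float(
                cfg.get("params", {}).get("d_refrac_ventricle_s", 0.25)
            ),
        )
        model = build_pvc_conduction(pvc_params)
        pvc_cfg = cfg.get("pvc_trigger", {})
        if "path" in pvc_cfg:
            pvc_times = read_trace_csv(pvc_cfg["path"])[
                pvc_cfg.get("port", "model.pvc")
            ]
        else:
            pvc_times = tuple(float(t) for t in pvc_cfg.get("times_s", ()))
        traces = simulate(model, sim_config, {"model.inp": sa, "model.pvc": pvc_times})
        interbeat = interbeat_samples(traces)
    elif model_kind == "monolithic":
        v, interbeat = monolithic_simulate(params, sa, sim_config)
        traces = TraceSet(
            {Port("model", "inp"): sa, Port("model", "outp"): v}
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    if cfg.get("compare", False):
        if model_kind != "modular":
            raise ValueError("compare mode requires model: modular")
        _, mono_interbeat = monolithic_simulate(params, sa, sim_config)
        comparison = compare_interbeat(
            interbeat, mono_interbeat, float(cfg.get("tolerance_s", 1e-6))
        )

    provenance = {
        "package": "conductsim",
        "version": __version__,
        "seed": seed,
        "model": model_kind,
        "config": _jsonable(cfg),
    }
    result = ExperimentResult(traces, tuple(interbeat), cfg, provenance, comparison)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trace_csv(result.traces, out / "traces.csv")
        write_interbeat_csv(result.interbeat, out / "interbeat.csv")
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        if comparison is not None:
            write_interbeat_csv(mono_interbeat, out / "interbeat_monolithic.csv")
            report = {
                "n_matched": comparison.n_matched,
                "max_abs_diff_s": comparison.max_abs_diff,
                "divergences": [
                    {"time_s": t, "delta_s": None if math.isnan(d) else d}
                    for t, d in comparison.divergences
                ],
            }
            (out / "comparison.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
            )
    return result


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj
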