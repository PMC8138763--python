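"""Tidy trace tables, stimulus schedules, and JSON result I/O.

Traces are stored long-format: one row per sample with columns
``cell_id, channel, compartment, time_s, intensity``.  A stimulus
schedule (ligand/inhibitor additions, blue-light windows) lives in a
separate JSON document so one schedule can serve many cells.  Times are
seconds everywhere; rates are s^-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("PM", "IM", "cytosol")
EVENT_KINDS = ("ligand_add", "inhibitor_add", "light_on", "light_off")
TRACE_COLUMNS = ("cell_id", "channel", "compartment", "time_s", "intensity")


class FormatError(ValueError):
    """A file does not have the documented layout (e.g. missing column)."""


class TraceValidationError(ValueError):
    """A trace violates its invariants (monotone time, nonnegative signal)."""


class ScheduleError(ValueError):
    """A stimulus schedule violates its invariants."""


@dataclass
class TimeSeriesTrace:
    """One cell x channel x compartment fluorescence time series.

    Parameters
    ----------
    cell_id : str
        Cell identifier.
    channel : str
        Sensor name, e.g. ``PH`` (PIP2 sensor), ``mGq``, ``b-arrestin2``,
        ``Gb1``, ``Gg9``, ``FRET-donor``, ``FRET-acceptor``.
    compartment : str
        One of ``PM``, ``IM``, ``cytosol``.
    time : ndarray
        Sample times in seconds, strictly increasing, length >= 2.
    intensity : ndarray
        Background-subtracted fluorescence, arbitrary units, >= 0.
    """

    cell_id: str
    channel: str
    compartment: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.compartment not in COMPARTMENTS:
            raise TraceValidationError(
                f"trace {self.key}: unknown compartment {self.compartment!r}"
            )
        if self.time.ndim != 1 or self.intensity.ndim != 1:
            raise TraceValidationError(f"trace {self.key}: arrays must be 1-D")
        if self.time.size != self.intensity.size:
            raise TraceValidationError(
                f"trace {self.key}: time and intensity lengths differ"
            )
        if self.time.size < 2:
            raise TraceValidationError(f"trace {self.key}: needs >= 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise TraceValidationError(
                f"trace {self.key}: time must be strictly increasing"
            )
        if np.any(self.intensity < 0):
            raise TraceValidationError(
                f"trace {self.key}: negative intensity values"
            )

    @property
    def key(self) -> tuple:
        return (self.cell_id, self.channel, self.compartment)

    def __len__(self) -> int:
        return self.time.size

    def value_at(self, t: float) -> float:
        """Linearly interpolated intensity at time ``t`` (no extrapolation)."""
        if t < self.time[0] or t > self.time[-1]:
            raise ValueError(f"t={t} outside trace time range")
        return float(np.interp(t, self.time, self.intensity))


@dataclass
class StimulusEvent:
    """A timed perturbation: ligand/inhibitor addition or a light edge."""

    time: float
    kind: str
    label: str = ""
    concentration: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScheduleError(f"unknown event kind {self.kind!r}")
        self.time = float(self.time)


@dataclass
class StimulusSchedule:
    """Ordered perturbation events driving an experiment."""

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError("event times must be nondecreasing")
        # light_on / light_off must strictly alternate per light source
        state: dict = {}
        for e in self.events:
            if e.kind in ("light_on", "light_off"):
                on = e.kind == "light_on"
                if state.get(e.label) is on:
                    raise ScheduleError(
                        f"light events for {e.label!r} do not alternate"
                    )
                state[e.label] = on

    def events_of(self, *kinds: str) -> list:
        return [e for e in self.events if e.kind in kinds]

    def first_time(self, *kinds: str) -> Optional[float]:
        evs = self.events_of(*kinds) if kinds else self.events
        return evs[0].time if evs else None

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "time_s": e.time,
                    "kind": e.kind,
                    "label": e.label,
                    "concentration": e.concentration,
                }
                for e in self.events
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(
            events=[
                StimulusEvent(
                    time=ev["time_s"],
                    kind=ev["kind"],
                    label=ev.get("label", ""),
                    concentration=ev.get("concentration"),
                )
                for ev in d["events"]
            ]
        )


@dataclass
class Experiment:
    """A set of traces plus the schedule that produced them."""

    traces: list
    schedule: StimulusSchedule
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise TraceValidationError("sampling_rate must be > 0")
        keys = [t.key for t in self.traces]
        if len(set(keys)) != len(keys):
            raise TraceValidationError("duplicate (cell, channel, compartment)")

    @property
    def cells(self) -> list:
        seen: dict = {}
        for t in self.traces:
            seen.setdefault(t.cell_id, None)
        return list(seen)

    def get(self, cell_id: str, channel: str, compartment: str) -> TimeSeriesTrace:
        for t in self.traces:
            if t.key == (cell_id, channel, compartment):
                return t
        raise KeyError((cell_id, channel, compartment))

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "channel": t.channel,
                    "compartment": t.compartment,
                    "time_s": t.time,
                    "intensity": t.intensity,
                }
            )
            for t in self.traces
        ]
        return pd.concat(frames, ignore_index=True)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_experiment(path, schedule_path=None) -> Experiment:
    """Read a tidy CSV/TSV trace table (plus optional JSON schedule).

    One :class:`TimeSeriesTrace` is built per ``(cell_id, channel,
    compartment)`` group, with rows sorted by time.  Duplicate sample
    times within a trace, non-monotone time, and negative intensities
    are rejected with errors naming the offending trace.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    traces = []
    for key, g in df.groupby(["cell_id", "channel", "compartment"], sort=True):
        dt = np.diff(g["time_s"].to_numpy())
        if np.any(dt == 0):
            raise TraceValidationError(f"trace {key}: duplicate time points")
        if np.any(dt < 0):
            raise TraceValidationError(
                f"trace {key}: time column is not sorted"
            )
        traces.append(
            TimeSeriesTrace(
                cell_id=str(key[0]),
                channel=str(key[1]),
                compartment=str(key[2]),
                time=g["time_s"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
            )
        )
    if not traces:
        raise FormatError(f"{path}: no trace rows")
    schedule = StimulusSchedule()
    if schedule_path is not None:
        with open(schedule_path) as fh:
            schedule = StimulusSchedule.from_dict(json.load(fh))
    dts = np.concatenate([np.diff(t.time) for t in traces])
    sampling_rate = 1.0 / float(np.median(dts))
    return Experiment(traces=traces, schedule=schedule, sampling_rate=sampling_rate)


def write_experiment(exp: Experiment, path, schedule_path=None) -> None:
    """Write an experiment back to the tidy long format (and schedule JSON)."""
    path = Path(path)
    exp.to_frame().to_csv(path, sep=_sep_for(path), index=False)
    if schedule_path is not None:
        with open(schedule_path, "w") as fh:
            json.dump(exp.schedule.to_dict(), fh, indent=1)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    with open(path, "w") as fh:
        json.dump(schedule.to_dict(), fh, indent=1)


def read_schedule(path) -> StimulusSchedule:
    with open(path) as fh:
        return StimulusSchedule.from_dict(json.load(fh))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Result (de)serialization.  Every pipeline result dataclass round-trips
# through JSON with an explicit type tag, units, and provenance block.

_UNITS = {
    "HillFit": {"p": "s^-1", "t_mid": "s", "a1": "F/F0", "a2": "F/F0"},
    "PhaseSyncResult": {"mean_pd": "deg", "pd_dispersion": "deg", "coherence_r": "1"},
    "PopulationPhaseSummary": {"mean_pd": "deg", "pd_dispersion": "deg"},
    "AdaptationSeries": {"time": "s", "adaptation_pct": "%"},
    "PMLossSeries": {"time": "s", "loss_pct": "%"},
    "CouplingRegression": {"slope": "%adaptation per %loss"},
    "RateComparison": {"group_means": "s^-1", "group_sds": "s^-1"},
    "FretResult": {"time": "s", "ratio": "donor/FRET"},
}


def _result_registry() -> dict:
    # imported lazily: these modules import trace_io themselves
    from . import fret, kinetics, phase_sync, preprocess

    types = [
        kinetics.HillFit,
        kinetics.RateComparison,
        kinetics.CouplingRegression,
        phase_sync.PhaseSyncResult,
        phase_sync.PopulationPhaseSummary,
        preprocess.AdaptationSeries,
        preprocess.PMLossSeries,
        fret.FretResult,
    ]
    return {t.__name__: t for t in types}


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return {"__complex__": True, "re": obj.real.tolist(), "im": obj.imag.tolist()}
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(result: Any, path, provenance: Optional[dict] = None) -> None:
    """Serialize a pipeline result dataclass to a typed JSON document."""
    name = type(result).__name__
    if name not in _result_registry():
        raise TypeError(f"{name} is not a declared pipeline result type")
    doc = {
        "type": name,
        "units": _UNITS.get(name, {}),
        "provenance": provenance or {},
        "data": _to_jsonable(dataclasses.asdict(result)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_results(path) -> Any:
    """Load a result JSON written by :func:`write_results`."""
    with open(path) as fh:
        doc = json.load(fh)
    cls = _result_registry()[doc["type"]]
    data = doc["data"]

    def _revive(value, typ):
        if isinstance(value, dict) and value.get("__complex__"):
            return np.array(value["re"]) + 1j * np.array(value["im"])
        if isinstance(value, list) and typ is np.ndarray:
            return np.asarray(value, dtype=float)
        return value

    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            typ = np.ndarray if "ndarray" in str(f.type) else None
            kwargs[f.name] = _revive(data[f.name], typ)
    return cls(**kwargs)
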