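"""Phenomenological single-cell trace generator.

Emulates the live-cell experiments this pipeline analyzes: a Gq-coupled
receptor triggers transient, near-complete PIP2 hydrolysis (read out as
cytosolic accumulation of a PH-domain sensor) that partially adapts to a
low-intensity steady state; a mini-Gq probe is recruited fast and stays,
beta-arrestin2 is recruited slowly (t1/2 ~ 738 s); the G-protein beta/gamma
dimer leaves the plasma membrane, with the percent adaptation of hydrolysis
linearly coupled to the percent PM loss; a Gq inhibitor restores baseline;
and optogenetic blue-light windows switch an extra Gbg supply on and off,
slowing recovery while the light is on.

The generator is deliberately *not* a mass-action model of the
Gaq-PLCb-Gbg complex: it reproduces observable trace shapes and printed
rates.  Recovery segments follow exactly the dose-response sigmoid the
fitting stage uses,

    F(t) = F_ss + (F_peak - F_ss) / (1 + 10**(p * (t - t_mid))),

so parameter recovery is an exact self-consistency test; an exponential
recovery mode exists to probe model mismatch.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .trace_io import (
    Experiment,
    ScheduleError,
    StimulusEvent,
    StimulusSchedule,
    TimeSeriesTrace,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class Pip2Params:
    """Kinetics of the PIP2-sensor (cytosolic PH) response.

    ``f_peak`` and the recovery Hill slope ``p`` default to the printed
    study regime (peak cytosolic fold-change 2.60; recovery rate
    1.27e-2 s^-1).  ``t_mid_offset`` places the recovery midpoint after
    the stimulus so the half-recovery time lands near 184 s.
    """

    f_peak: float = 2.60          # peak cytosolic fold-change (F/F0)
    f_ss: float = 1.80            # steady-state plateau after adaptation
    k_h: float = 0.05             # hydrolysis (rise) rate, s^-1
    p: float = 1.27e-2            # recovery Hill slope, s^-1
    t_mid_offset: float = 184.0   # recovery midpoint after stimulus, s
    second_f_ss: float = 2.00     # plateau after a second-receptor episode
    second_p: float = 6.51e-3     # slower adaptation of the rehydrolysis
    inhibitor_rate: float = 0.03  # decay to baseline on Gq inhibition, s^-1
    light_p: float = 2.55e-3      # recovery slope during continuous light
    post_light_p: float = 1.60e-2  # recovery slope after light-off
    post_light_t_mid_offset: float = 60.0
    recovery_shape: str = "sigmoid"  # or "exponential" (model mismatch mode)

    def validate(self) -> None:
        if not (self.f_peak > self.f_ss >= 1.0):
            raise ConfigError("require f_peak > f_ss >= 1")
        if not (1.0 <= self.second_f_ss < self.f_peak):
            raise ConfigError("require 1 <= second_f_ss < f_peak")
        for name in ("k_h", "p", "second_p", "inhibitor_rate", "light_p",
                     "post_light_p"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.recovery_shape not in ("sigmoid", "exponential"):
            raise ConfigError("recovery_shape must be sigmoid|exponential")


@dataclass
class GbgParams:
    """PM loss of the beta/gamma dimer and its coupling to adaptation.

    ``max_loss_pct`` defaults to the ~40% PM loss observed at peak
    hydrolysis.  During recovery, loss%(t) is constructed so that
    adaptation% = coupling_m * (loss% - loss at peak) exactly; the
    noiseless regression of adaptation on loss therefore has R^2 = 1 and
    slope ``coupling_m``.  The g9/g3 presets differ only in loss rate
    and magnitude (low- vs high-PM-affinity gamma subtypes); their
    numeric values are package choices.
    """

    max_loss_pct: float = 40.0
    loss_rate: float = 0.03       # pre-peak PM loss rate, s^-1
    coupling_m: float = 2.5       # adaptation% per loss% during recovery
    im_gain: float = 1.0          # IM accumulation per unit PM loss

    def validate(self) -> None:
        if not (0.0 <= self.max_loss_pct <= 100.0):
            raise ConfigError("max_loss_pct must be in [0, 100]")
        if self.loss_rate <= 0 or self.coupling_m <= 0:
            raise ConfigError("loss_rate and coupling_m must be > 0")

    @classmethod
    def preset(cls, gamma_type: str) -> "GbgParams":
        if gamma_type == "g9":   # low PM affinity: fast, larger loss
            return cls(max_loss_pct=40.0, loss_rate=0.03, coupling_m=2.5)
        if gamma_type == "g3":   # high PM affinity: slow, smaller loss
            return cls(max_loss_pct=25.0, loss_rate=0.008, coupling_m=4.0)
        raise ConfigError(f"unknown gamma preset {gamma_type!r}")


@dataclass
class NoiseParams:
    """Measurement noise: dominant multiplicative (shot/expression) term,
    small additive term, optional linear bleach drift."""

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.005
    bleach_per_100s: float = 0.0   # fractional intensity loss per 100 s

    def validate(self) -> None:
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ConfigError("noise sd must be >= 0")

    @property
    def is_zero(self) -> bool:
        return (self.multiplicative_sd == 0 and self.additive_sd == 0
                and self.bleach_per_100s == 0)


def default_schedule(stim_time: float = 60.0) -> StimulusSchedule:
    return StimulusSchedule(
        events=[StimulusEvent(time=stim_time, kind="ligand_add",
                              label="bombesin", concentration="1 uM")]
    )


@dataclass
class SimulationConfig:
    """Full description of a simulated experiment (seeded, deterministic)."""

    n_cells: int = 20
    duration: float = 600.0
    sampling_rate: float = 2.0
    schedule: StimulusSchedule = field(default_factory=default_schedule)
    pip2: Pip2Params = field(default_factory=Pip2Params)
    arrestin_t_half: float = 738.0   # slow recruitment half-time, s
    arrestin_tau: float = 150.0      # logistic rise time constant, s
    arrestin_max: float = 0.5        # fractional cytosolic loss at plateau
    mgq_rate: float = 0.05           # fast receptor-probe recruitment, s^-1
    mgq_max: float = 0.4             # fractional cytosolic loss at plateau
    gbg: GbgParams = field(default_factory=GbgParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    cell_cv: float = 0.2             # lognormal CV of per-cell kinetics
    base_intensity: float = 200.0    # raw fluorescence scale, a.u.
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("duration and sampling_rate must be > 0")
        for name in ("arrestin_t_half", "arrestin_tau", "mgq_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.cell_cv < 0:
            raise ConfigError("cell_cv must be >= 0")
        self.pip2.validate()
        self.gbg.validate()
        self.noise.validate()
        for e in self.schedule.events:
            if not (0.0 <= e.time <= self.duration):
                raise ScheduleError(
                    f"event at t={e.time}s outside [0, {self.duration}]s"
                )

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration * self.sampling_rate)) + 1
        return np.arange(n) / self.sampling_rate


@dataclass
class CellParams:
    """Per-cell realized kinetic parameters (ground truth for one cell)."""

    pip2: Pip2Params
    gbg: GbgParams
    arrestin_t_half: float
    arrestin_tau: float
    arrestin_max: float
    mgq_rate: float
    mgq_max: float


@dataclass
class GroundTruth:
    """Realized per-cell parameters for every generated cell."""

    cells: dict  # cell_id -> CellParams

    def slopes(self) -> np.ndarray:
        """Realized recovery Hill slopes, s^-1 (one per cell)."""
        return np.array([cp.pip2.p for cp in self.cells.values()])


# ---------------------------------------------------------------------------
# trace shapes

def _approach(v0: float, target: float, rate: float, t0: float) -> Callable:
    def f(ts: np.ndarray) -> np.ndarray:
        return target + (v0 - target) * np.exp(-rate * (ts - t0))
    return f


def _episode(v0: float, t0: float, pp: Pip2Params, f_ss: float, p: float,
             t_mid_offset: float) -> Callable:
    """Hydrolysis episode: exponential rise toward f_peak capped by the
    recovery curve; the recovery limb is exactly the fitted sigmoid."""
    rise = _approach(v0, pp.f_peak, pp.k_h, t0)
    t_mid = t0 + t_mid_offset
    if pp.recovery_shape == "sigmoid":
        def rec(ts: np.ndarray) -> np.ndarray:
            return f_ss + (pp.f_peak - f_ss) / (1.0 + 10.0 ** (p * (ts - t_mid)))
    else:  # exponential model-mismatch mode, matched decade rate
        k = p * np.log(10.0)
        def rec(ts: np.ndarray) -> np.ndarray:
            return f_ss + (pp.f_peak - f_ss) * np.minimum(
                1.0, np.exp(-k * (ts - t_mid)))
    def f(ts: np.ndarray) -> np.ndarray:
        return np.minimum(rise(ts), rec(ts))
    return f


def _anchored_decay(v0: float, t0: float, f_ss: float, p: float,
                    t_mid_offset: float) -> Callable:
    """Sigmoid decay from v0 toward f_ss, continuous at t0 and exactly of
    the dose-response form (upper asymptote adjusted to pass through v0)."""
    t_mid = t0 + t_mid_offset
    a2 = f_ss + (v0 - f_ss) * (1.0 + 10.0 ** (-p * t_mid_offset))
    def f(ts: np.ndarray) -> np.ndarray:
        return f_ss + (a2 - f_ss) / (1.0 + 10.0 ** (p * (ts - t_mid)))
    return f


def pip2_shape(time: np.ndarray, pp: Pip2Params,
               schedule: StimulusSchedule) -> np.ndarray:
    """Noiseless normalized (F/F0) PIP2-sensor trajectory for a schedule."""
    if not schedule.events_of("ligand_add", "light_on"):
        raise ScheduleError("schedule needs >= 1 ligand_add or light_on event")
    cur: Callable = lambda ts: np.ones_like(ts)
    segments = []  # (t_start, fn)
    segments.append((-np.inf, cur))
    n_ligand = 0
    for e in schedule.events:
        v0 = float(cur(np.array([e.time]))[0])
        if e.kind == "ligand_add":
            n_ligand += 1
            if n_ligand == 1:
                cur = _episode(v0, e.time, pp, pp.f_ss, pp.p, pp.t_mid_offset)
            else:
                cur = _episode(v0, e.time, pp, pp.second_f_ss, pp.second_p,
                               pp.t_mid_offset)
        elif e.kind == "light_on":
            cur = _episode(v0, e.time, pp, pp.f_ss, pp.light_p,
                           pp.t_mid_offset)
        elif e.kind == "light_off":
            cur = _anchored_decay(v0, e.time, pp.f_ss, pp.post_light_p,
                                  pp.post_light_t_mid_offset)
        elif e.kind == "inhibitor_add":
            cur = _approach(v0, 1.0, pp.inhibitor_rate, e.time)
        segments.append((e.time, cur))
    values = np.empty_like(time)
    bounds = [s[0] for s in segments] + [np.inf]
    for i, (t_start, fn) in enumerate(segments):
        mask = (time >= t_start) & (time < bounds[i + 1])
        values[mask] = fn(time[mask])
    return values


def _apply_noise(values: np.ndarray, time: np.ndarray, noise: NoiseParams,
                 rng: Optional[np.random.Generator]) -> np.ndarray:
    if rng is None or noise.is_zero:
        return values
    v = values * (1.0 + rng.normal(0.0, noise.multiplicative_sd, values.size))
    v = v + rng.normal(0.0, noise.additive_sd, values.size)
    v = v * (1.0 - noise.bleach_per_100s * time / 100.0)
    n_clip = int(np.sum(v < 0))
    if n_clip:
        log.info("clipped %d negative samples after noise", n_clip)
    return np.clip(v, 0.0, None)


def simulate_pip2_trace(config: SimulationConfig,
                        cell_params: Optional[CellParams] = None,
                        cell_id: str = "cell000",
                        rng: Optional[np.random.Generator] = None,
                        ) -> TimeSeriesTrace:
    """Simulate the cytosolic PIP2-sensor (PH) trace for one cell."""
    config.validate()
    pp = cell_params.pip2 if cell_params is not None else config.pip2
    t = config.time_grid()
    shape = pip2_shape(t, pp, config.schedule)
    shape = _apply_noise(shape, t, config.noise, rng)
    return TimeSeriesTrace(cell_id=cell_id, channel="PH",
                           compartment="cytosol", time=t,
                           intensity=config.base_intensity * shape)


def _saturating(t: np.ndarray, t0: float, rate: float) -> np.ndarray:
    s = 1.0 - np.exp(-rate * (t - t0))
    return np.where(t >= t0, s, 0.0)


def _logistic_rise(t: np.ndarray, t0: float, t_half: float,
                   tau: float) -> np.ndarray:
    sig = 1.0 / (1.0 + np.exp(-((t - t0) - t_half) / tau))
    sig0 = 1.0 / (1.0 + np.exp(t_half / tau))
    s = (sig - sig0) / (1.0 - sig0)
    return np.where(t >= t0, s, 0.0)


def simulate_companion_traces(config: SimulationConfig,
                              cell_params: CellParams,
                              pip2_trace: TimeSeriesTrace,
                              rng: Optional[np.random.Generator] = None,
                              ) -> list:
    """Simulate mGq, beta-arrestin2, Gb (PM) and Gg (IM) traces for the
    cell that produced ``pip2_trace``.

    The mGq probe saturates quickly at stimulus onset (phase-locked with
    hydrolysis); arrestin recruits slowly (logistic, configured t1/2);
    the Gb PM trace loses intensity with adaptation%/loss% coupled
    linearly; the Gg IM trace mirrors the PM loss.
    """
    if pip2_trace is None:
        raise ValueError("pip2_trace is required")
    config.validate()
    cp = cell_params
    t = pip2_trace.time
    t0 = config.schedule.first_time("ligand_add", "light_on")
    cell = pip2_trace.cell_id

    sat = _saturating(t, t0, cp.mgq_rate)
    log_rise = _logistic_rise(t, t0, cp.arrestin_t_half, cp.arrestin_tau)

    shapes = {
        ("mGq", "cytosol"): 1.0 - cp.mgq_max * sat,
        ("mGq", "PM"): 1.0 + cp.mgq_max * sat,
        ("b-arrestin2", "cytosol"): 1.0 - cp.arrestin_max * log_rise,
        ("b-arrestin2", "PM"): 1.0 + cp.arrestin_max * log_rise,
    }

    # Gbg PM loss: ramp to the at-peak loss during hydrolysis, then move
    # linearly with the adaptation fraction of the noiseless PIP2 shape.
    pp = cp.pip2
    shape0 = pip2_shape(t, pp, config.schedule)
    i_peak = int(np.argmax(shape0))
    t_peak = t[i_peak]
    f_pk = shape0[i_peak]
    adaptation = np.zeros_like(t)
    if f_pk > 1.0:
        post = t >= t_peak
        adaptation[post] = 100.0 * (f_pk - shape0[post]) / (f_pk - 1.0)
    a_plateau = 100.0 * (pp.f_peak - pp.f_ss) / (pp.f_peak - 1.0)
    loss_at_peak = max(0.0, cp.gbg.max_loss_pct - a_plateau / cp.gbg.coupling_m)
    loss = loss_at_peak * _saturating(t, t0, cp.gbg.loss_rate)
    post = t >= t_peak
    loss[post] = loss_at_peak + adaptation[post] / cp.gbg.coupling_m
    loss = np.clip(loss, 0.0, cp.gbg.max_loss_pct)
    shapes[("Gb1", "PM")] = 1.0 - loss / 100.0
    shapes[("Gg9", "IM")] = 1.0 + cp.gbg.im_gain * loss / 100.0

    traces = []
    for (channel, compartment), shape in shapes.items():
        noisy = _apply_noise(shape, t, config.noise, rng)
        traces.append(TimeSeriesTrace(
            cell_id=cell, channel=channel, compartment=compartment,
            time=t, intensity=config.base_intensity * noisy))
    return traces


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def draw_cell_params(config: SimulationConfig,
                     rng: np.random.Generator) -> CellParams:
    """Draw one cell's kinetics lognormally around the config means."""
    cv = config.cell_cv
    f = lambda: _lognormal_factor(rng, cv)
    pp = config.pip2
    excess = (pp.f_peak - 1.0) * f()     # scale the response amplitude
    frac_ss = (pp.f_ss - 1.0) / (pp.f_peak - 1.0)
    frac_2nd = (pp.second_f_ss - 1.0) / (pp.f_peak - 1.0)
    pip2 = replace(
        pp,
        f_peak=1.0 + excess,
        f_ss=1.0 + frac_ss * excess,
        second_f_ss=1.0 + frac_2nd * excess,
        k_h=pp.k_h * f(),
        p=pp.p * f(),
        second_p=pp.second_p * f(),
        light_p=pp.light_p * f(),
        post_light_p=pp.post_light_p * f(),
    )
    gbg = replace(config.gbg, loss_rate=config.gbg.loss_rate * f())
    return CellParams(
        pip2=pip2,
        gbg=gbg,
        arrestin_t_half=config.arrestin_t_half * f(),
        arrestin_tau=config.arrestin_tau,
        arrestin_max=config.arrestin_max,
        mgq_rate=config.mgq_rate * f(),
        mgq_max=config.mgq_max,
    )


def simulate_population(config: SimulationConfig) -> tuple:
    """Simulate ``n_cells`` cells; returns ``(Experiment, GroundTruth)``.

    Deterministic: identical (seed, config) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    traces, cells = [], {}
    for i in range(config.n_cells):
        cell_id = f"cell{i:03d}"
        cp = draw_cell_params(config, rng)
        cells[cell_id] = cp
        pip2 = simulate_pip2_trace(config, cp, cell_id=cell_id, rng=rng)
        traces.append(pip2)
        traces.extend(simulate_companion_traces(config, cp, pip2, rng=rng))
    exp = Experiment(traces=traces, schedule=config.schedule,
                     sampling_rate=config.sampling_rate,
                     metadata={"seed": config.seed, "n_cells": config.n_cells})
    return exp, GroundTruth(cells=cells)
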