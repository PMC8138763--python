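"""Baseline normalization, uniform-grid spline resampling, and the
percentage metrics (% adaptation of hydrolysis, % PM loss).

All downstream analyses operate on F/F0 traces: each sample divided by
the mean intensity over a pre-stimulus baseline window.  Both percentage
metrics are invariant to rescaling the raw trace by a positive constant.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .trace_io import StimulusSchedule, TimeSeriesTrace, TraceValidationError

log = logging.getLogger(__name__)


class NoResponseError(ValueError):
    """Post-stimulus trace is flat: no peak to anchor the 0% adaptation."""


@dataclass
class NormalizedTrace(TimeSeriesTrace):
    """A trace whose intensity is F/F0 (dimensionless).

    ``f0`` is the mean raw intensity over ``baseline_window`` (seconds).
    """

    f0: float = 1.0
    baseline_window: Tuple[float, float] = (0.0, 0.0)


@dataclass
class AdaptationSeries:
    """Percent adaptation of hydrolysis vs. time.

    0% at the post-stimulus peak (maximum hydrolysis), 100% when the
    sensor returns to baseline.  Values may exceed 100% if the trace
    overshoots baseline (e.g. full recovery after Gq inhibition); they
    are reported unclipped with ``exceeds_100`` set.
    """

    time: np.ndarray
    adaptation_pct: np.ndarray
    t_peak: float
    f_peak: float
    f_baseline: float = 1.0
    exceeds_100: bool = False
    cell_id: str = ""


@dataclass
class PMLossSeries:
    """Percent loss of a PM-resident sensor relative to preactivation."""

    time: np.ndarray
    loss_pct: np.ndarray
    n_clipped_negative: int = 0
    cell_id: str = ""


def default_baseline_window(trace: TimeSeriesTrace,
                            schedule: StimulusSchedule) -> Tuple[float, float]:
    """[trace start, first scheduled event): the pre-stimulus segment."""
    t_first = schedule.first_time()
    if t_first is None or t_first <= trace.time[0]:
        raise ValueError("schedule has no event after trace start")
    return (float(trace.time[0]), float(t_first))


def normalize_trace(trace: TimeSeriesTrace,
                    baseline_window: Optional[Tuple[float, float]] = None,
                    schedule: Optional[StimulusSchedule] = None,
                    ) -> NormalizedTrace:
    """Divide a trace by its mean intensity over the baseline window."""
    if baseline_window is None:
        if schedule is None:
            raise ValueError("provide baseline_window or schedule")
        baseline_window = default_baseline_window(trace, schedule)
    t0, t1 = baseline_window
    mask = (trace.time >= t0) & (trace.time < t1)
    if mask.sum() < 2:
        raise ValueError(
            f"baseline window [{t0}, {t1}) holds {int(mask.sum())} samples; need >= 2"
        )
    f0 = float(trace.intensity[mask].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean {f0} must be > 0")
    return NormalizedTrace(
        cell_id=trace.cell_id, channel=trace.channel,
        compartment=trace.compartment, time=trace.time.copy(),
        intensity=trace.intensity / f0, f0=f0,
        baseline_window=(float(t0), float(t1)),
    )


def resample_uniform(trace: TimeSeriesTrace, rate: float,
                     t_start: Optional[float] = None,
                     t_end: Optional[float] = None) -> TimeSeriesTrace:
    """Natural cubic-spline resampling onto a uniform grid.

    The grid starts at ``t_start`` (default: the trace's first sample)
    and steps by 1/rate up to ``t_end``; no extrapolation beyond the
    data range is allowed.  Knot values are reproduced exactly, so
    resampling an already-uniform trace at its own rate is the identity.
    """
    if len(trace) < 4:
        raise ValueError("cubic spline resampling needs >= 4 samples")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    lo, hi = float(trace.time[0]), float(trace.time[-1])
    t_start = lo if t_start is None else float(t_start)
    t_end = hi if t_end is None else float(t_end)
    if t_start < lo - 1e-9 or t_end > hi + 1e-9:
        raise ValueError(
            f"requested grid [{t_start}, {t_end}] outside data range [{lo}, {hi}]"
        )
    n = int(np.floor((t_end - t_start) * rate + 1e-9)) + 1
    grid = t_start + np.arange(n) / rate
    spline = CubicSpline(trace.time, trace.intensity, bc_type="natural")
    values = spline(grid)
    n_neg = int(np.sum(values < 0))
    if n_neg:
        log.info("resample_uniform: clipped %d negative spline values", n_neg)
        values = np.clip(values, 0.0, None)
    return dataclasses.replace(trace, time=grid, intensity=values)


def percent_adaptation(norm: NormalizedTrace, stim_time: float,
                       search_end: Optional[float] = None,
                       response_tol: float = 0.05,
                       cytosolic_rising: Optional[bool] = None,
                       ) -> AdaptationSeries:
    """Percent adaptation, anchored at the post-stimulus extremum.

    The peak is the first global extremum of |F - 1| after ``stim_time``
    (within ``[stim_time, search_end]``).  For a cytosolic sensor that
    rises on hydrolysis, adaptation% = 100 (F_peak - F) / (F_peak - 1);
    the sign-mirrored form is used for sensors that fall on stimulation.
    """
    t, f = norm.time, norm.intensity
    post = t >= stim_time
    if search_end is not None:
        post &= t <= search_end
    if post.sum() < 2:
        raise ValueError("no post-stimulus samples in search window")
    dev = np.abs(f[post] - 1.0)
    if dev.max() < response_tol:
        raise NoResponseError(
            f"trace {norm.key}: post-stimulus |F-1| < {response_tol} (no response)"
        )
    i_peak_local = int(np.argmax(dev))  # argmax returns the first maximum
    i_peak = np.flatnonzero(post)[i_peak_local]
    f_peak = float(f[i_peak])
    rising = f_peak > 1.0 if cytosolic_rising is None else cytosolic_rising
    sel = t >= t[i_peak]
    if rising:
        pct = 100.0 * (f_peak - f[sel]) / (f_peak - 1.0)
    else:
        pct = 100.0 * (f[sel] - f_peak) / (1.0 - f_peak)
    return AdaptationSeries(
        time=t[sel].copy(), adaptation_pct=pct, t_peak=float(t[i_peak]),
        f_peak=f_peak, exceeds_100=bool(np.any(pct > 100.0)),
        cell_id=norm.cell_id,
    )


def percent_pm_loss(norm: NormalizedTrace, stim_time: float) -> PMLossSeries:
    """Percent loss of a PM sensor: 100 (1 - F), 0% at preactivation.

    Transient negatives (F briefly above the preactivation level) are
    clipped to 0 and counted.
    """
    if norm.compartment != "PM":
        raise TraceValidationError(
            f"percent_pm_loss expects a PM trace, got {norm.compartment!r}"
        )
    if not np.any(norm.time < stim_time):
        raise ValueError("no preactivation samples before stim_time")
    loss = 100.0 * (1.0 - norm.intensity)
    n_neg = int(np.sum(loss < 0))
    if n_neg:
        log.info("percent_pm_loss: clipped %d transient negative losses", n_neg)
    return PMLossSeries(time=norm.time.copy(),
                        loss_pct=np.clip(loss, 0.0, None),
                        n_clipped_negative=n_neg, cell_id=norm.cell_id)
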