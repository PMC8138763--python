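"""Convenience orchestration over the analysis stages.

These helpers wire the module-level operations together the way the CLI
and a typical notebook session use them: normalize against the
pre-stimulus baseline, pick the recovery window (post-stimulus peak to
the next scheduled event), fit the dose-response slope, pair channels
for phase synchronization, and pool the adaptation/PM-loss coupling.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from . import kinetics, phase_sync, preprocess
from .trace_io import Experiment, StimulusSchedule, TimeSeriesTrace


def stimulus_time(schedule: StimulusSchedule) -> float:
    t = schedule.first_time("ligand_add", "light_on")
    if t is None:
        raise ValueError("schedule has no stimulating event")
    return t


def normalized(exp: Experiment, cell: str, channel: str,
               compartment: str) -> preprocess.NormalizedTrace:
    trace = exp.get(cell, channel, compartment)
    return preprocess.normalize_trace(trace, schedule=exp.schedule)


def recovery_window(norm: preprocess.NormalizedTrace,
                    schedule: StimulusSchedule) -> Tuple[float, float]:
    """Default fit window: post-stimulus peak to the next event (or end)."""
    stim = stimulus_time(schedule)
    adapt = preprocess.percent_adaptation(norm, stim)
    later = [e.time for e in schedule.events if e.time > adapt.t_peak]
    t_end = min(later) if later else float(norm.time[-1])
    return (adapt.t_peak, t_end)


def recovery_fits(exp: Experiment, channel: str = "PH",
                  compartment: str = "cytosol",
                  window: Optional[Tuple[float, float]] = None,
                  ) -> Dict[str, kinetics.HillFit]:
    """Per-cell recovery Hill-slope fits for one sensor channel."""
    fits = {}
    for cell in exp.cells:
        norm = normalized(exp, cell, channel, compartment)
        w = window if window is not None else recovery_window(norm, exp.schedule)
        fits[cell] = kinetics.fit_dose_response(norm, window=w)
    return fits


def pair_phase(exp: Experiment, cell: str,
               pair_a: Tuple[str, str], pair_b: Tuple[str, str],
               rate: Optional[float] = None,
               detrend: Optional[str] = "linear",
               convention: str = "wrapped") -> phase_sync.PhaseSyncResult:
    """Phase difference between two channels of one cell.

    ``pair_a``/``pair_b`` are (channel, compartment).  Both traces are
    normalized, spline-resampled onto a shared uniform grid (the coarser
    of the two native rates over the overlapping span), and passed
    through the Hilbert phase analysis.
    """
    na = normalized(exp, cell, *pair_a)
    nb = normalized(exp, cell, *pair_b)
    if rate is None:
        rates = [1.0 / np.median(np.diff(n.time)) for n in (na, nb)]
        rate = min(rates)
    lo = max(na.time[0], nb.time[0])
    hi = min(na.time[-1], nb.time[-1])
    ra = preprocess.resample_uniform(na, rate, t_start=lo, t_end=hi)
    rb = preprocess.resample_uniform(nb, rate, t_start=lo, t_end=hi)
    pa = phase_sync.instantaneous_phase(ra, detrend=detrend)
    pb = phase_sync.instantaneous_phase(rb, detrend=detrend)
    return phase_sync.phase_difference(pa, pb, convention=convention)


def population_pair_phase(exp: Experiment,
                          pair_a: Tuple[str, str], pair_b: Tuple[str, str],
                          convention: str = "wrapped",
                          ) -> phase_sync.PopulationPhaseSummary:
    results = [pair_phase(exp, cell, pair_a, pair_b, convention=convention)
               for cell in exp.cells]
    return phase_sync.population_phase_summary(results)


def adaptation_loss_regression(exp: Experiment, cell: str,
                               sensor: Tuple[str, str] = ("PH", "cytosol"),
                               pm_channel: str = "Gb1",
                               ) -> kinetics.CouplingRegression:
    """Adaptation% vs PM-loss% regression for one cell."""
    stim = stimulus_time(exp.schedule)
    norm_pip2 = normalized(exp, cell, *sensor)
    norm_pm = normalized(exp, cell, pm_channel, "PM")
    adapt = preprocess.percent_adaptation(norm_pip2, stim)
    loss = preprocess.percent_pm_loss(norm_pm, stim)
    return kinetics.correlate_adaptation_loss(adapt, loss)


def pooled_adaptation_loss_regression(exp: Experiment,
                                      sensor: Tuple[str, str] = ("PH", "cytosol"),
                                      pm_channel: str = "Gb1",
                                      mode: str = "mean_curve",
                                      ) -> kinetics.CouplingRegression:
    """Adaptation% vs PM-loss% regression across the population.

    ``mode="mean_curve"`` (default) regresses the cell-averaged
    adaptation time course on the cell-averaged loss time course — the
    population-average presentation this analysis is usually plotted
    with.  ``mode="pooled"`` stacks every cell's paired samples instead.
    """
    from scipy import stats

    stim = stimulus_time(exp.schedule)
    xs, ys = [], []
    for cell in exp.cells:
        adapt = preprocess.percent_adaptation(
            normalized(exp, cell, *sensor), stim)
        loss = preprocess.percent_pm_loss(
            normalized(exp, cell, pm_channel, "PM"), stim)
        common, ia, il = np.intersect1d(adapt.time, loss.time,
                                        return_indices=True)
        xs.append((common, loss.loss_pct[il]))
        ys.append((common, adapt.adaptation_pct[ia]))
    if mode == "mean_curve":
        # restrict to times where every cell has a defined adaptation
        shared = xs[0][0]
        for common, _ in xs[1:]:
            shared = np.intersect1d(shared, common)
        x = np.mean([np.interp(shared, c, v) for c, v in xs], axis=0)
        y = np.mean([np.interp(shared, c, v) for c, v in ys], axis=0)
        n = int(shared.size)
    elif mode == "pooled":
        x = np.concatenate([v for _, v in xs])
        y = np.concatenate([v for _, v in ys])
        n = int(x.size)
    else:
        raise ValueError("mode must be 'mean_curve' or 'pooled'")
    res = stats.linregress(x, y)
    return kinetics.CouplingRegression(slope=float(res.slope),
                                       intercept=float(res.intercept),
                                       r_squared=float(res.rvalue ** 2),
                                       n=n)
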