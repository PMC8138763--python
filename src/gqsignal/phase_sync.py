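"""Hilbert-transform phase synchronization between paired responses.

For two uniformly sampled, zero-mean signals x(t) and y(t), the analytic
signal (signal + i * Hilbert transform) gives an instantaneous phase at
every sample.  The per-timepoint phase difference

    dPhi_p = Phi_x(t_p) - Phi_y(t_p),   p = 1 .. T

is wrapped to [0 deg, 360 deg) and summarized by its circular mean, and
the phase coherence is the mean resultant length of the dPhi distribution
projected onto the unit circle,

    R = | (1/T) * sum_p exp(i * dPhi_p) |  =  1 - circular variance,

the standard phase-locking value: R = 1 for perfect locking, R -> 0 for
uniformly scattered phase differences.

Traces are linearly detrended by default (the analytic-signal phase is
meaningful only for zero-mean signals) and reflection-padded by 10% of
their length before the transform to suppress edge artifacts (the
reflection is point-symmetric about each endpoint, which leaves the
interior of periodic signals undistorted); samples in the outer 10% at
each end are flagged as edge samples and excluded from the scalar
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import detrend as _sp_detrend
from scipy.signal import hilbert as _sp_hilbert

from .trace_io import TimeSeriesTrace


class ZeroAmplitudeError(ValueError):
    """Constant trace: the analytic signal has no defined phase."""


class GridMismatchError(ValueError):
    """Paired phase series do not share a time grid."""


@dataclass
class PhaseSeries:
    """Instantaneous phase and envelope of one trace."""

    time: np.ndarray
    phase_wrapped: np.ndarray      # radians in [0, 2*pi)
    phase_unwrapped: np.ndarray    # radians, continuous
    amplitude: np.ndarray          # analytic-signal envelope, >= 0
    interior: np.ndarray           # False on edge samples
    cell_id: str = ""
    channel: str = ""

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(self.phase_wrapped)


@dataclass
class PhaseSyncResult:
    """Phase differences between one pair of responses (one cell)."""

    time: np.ndarray
    pd_series: np.ndarray          # degrees in [0, 360)
    mean_pd: float                 # circular mean, degrees in [0, 360)
    pd_dispersion: float           # circular SD, degrees
    coherence_r: float             # mean resultant length in [0, 1]
    unit_circle: np.ndarray        # complex exp(i * dPhi), interior samples
    n_timepoints: int
    convention: str = "wrapped"    # or "absolute" ([0, 180] folding)
    cell_id: str = ""
    pair: str = ""


@dataclass
class PopulationPhaseSummary:
    """Circular summary of per-cell mean phase differences."""

    mean_pd: float                 # degrees in [0, 360)
    pd_dispersion: float           # circular SD, degrees
    n_cells: int
    per_cell_pd: np.ndarray        # degrees
    per_cell_vectors: np.ndarray   # complex unit vectors for plotting


def _check_uniform(time: np.ndarray) -> None:
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("time grid is not uniform; resample first")


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, mapped to [0, 360)."""
    z = np.mean(np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float))))
    d = float(np.degrees(np.angle(z)) % 360.0)
    return 0.0 if d >= 360.0 else d   # guard the -0.0 wrap


def circular_sd_deg(angles_deg: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    r = np.abs(np.mean(np.exp(1j * np.radians(np.asarray(angles_deg)))))
    r = min(max(r, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def instantaneous_phase(trace: TimeSeriesTrace,
                        detrend: Optional[str] = "linear",
                        pad_frac: float = 0.1,
                        edge_frac: float = 0.1) -> PhaseSeries:
    """Instantaneous Hilbert phase and envelope of a uniform-grid trace.

    ``detrend`` is ``"linear"`` (default), ``"mean"``, or ``None`` (use
    the raw samples; caller guarantees zero mean).  ``pad_frac`` controls
    mirror padding before the transform; ``edge_frac`` of samples at each
    end are flagged as edge-affected.
    """
    if len(trace) < 16:
        raise ValueError("need >= 16 samples for a meaningful phase")
    _check_uniform(trace.time)
    x = trace.intensity.astype(float)
    if np.ptp(x) == 0:
        raise ZeroAmplitudeError(f"trace {trace.key} is constant")
    if detrend == "linear":
        x = _sp_detrend(x, type="linear")
    elif detrend == "mean":
        x = x - x.mean()
    elif detrend is not None:
        raise ValueError("detrend must be 'linear', 'mean', or None")
    n = x.size
    n_pad = int(round(pad_frac * n))
    if n_pad > 0:
        # point-symmetric (odd) reflection: continuous in value and slope
        # direction, so a sinusoid's interior envelope stays undistorted
        left = 2.0 * x[0] - x[1:n_pad + 1][::-1]
        right = 2.0 * x[-1] - x[-n_pad - 1:-1][::-1]
        xp = np.concatenate([left, x, right])
        analytic = _sp_hilbert(xp)[n_pad:n_pad + n]
    else:
        analytic = _sp_hilbert(x)
    phase = np.angle(analytic)
    n_edge = int(round(edge_frac * n))
    interior = np.ones(n, dtype=bool)
    if n_edge > 0:
        interior[:n_edge] = False
        interior[-n_edge:] = False
    return PhaseSeries(
        time=trace.time.copy(),
        phase_wrapped=phase % (2.0 * np.pi),
        phase_unwrapped=np.unwrap(phase),
        amplitude=np.abs(analytic),
        interior=interior,
        cell_id=trace.cell_id,
        channel=trace.channel,
    )


def phase_difference(x: PhaseSeries, y: PhaseSeries,
                     convention: str = "wrapped") -> PhaseSyncResult:
    """Per-timepoint phase difference Phi_x - Phi_y and its circular summary.

    ``convention="wrapped"`` reports angles in [0 deg, 360 deg);
    ``"absolute"`` folds them to [0 deg, 180 deg].  Scalar summaries
    (mean, dispersion, coherence) use interior samples only.
    """
    if x.time.size != y.time.size or not np.allclose(x.time, y.time):
        raise GridMismatchError("phase series are on different time grids")
    if convention not in ("wrapped", "absolute"):
        raise ValueError("convention must be 'wrapped' or 'absolute'")
    dphi = (x.phase_wrapped - y.phase_wrapped) % (2.0 * np.pi)
    pd_deg = np.degrees(dphi)
    if convention == "absolute":
        pd_deg = np.minimum(pd_deg, 360.0 - pd_deg)
    interior = x.interior & y.interior
    core = pd_deg[interior] if interior.any() else pd_deg
    mean_pd = circular_mean_deg(core)
    if convention == "absolute":
        mean_pd = min(mean_pd, 360.0 - mean_pd)
    vectors = np.exp(1j * np.radians(core))
    return PhaseSyncResult(
        time=x.time.copy(),
        pd_series=pd_deg,
        mean_pd=mean_pd,
        pd_dispersion=circular_sd_deg(core),
        coherence_r=float(np.abs(vectors.mean())),
        unit_circle=vectors,
        n_timepoints=int(pd_deg.size),
        convention=convention,
        cell_id=x.cell_id or y.cell_id,
        pair=f"{x.channel}:{y.channel}",
    )


def phase_coherence(result_or_pd) -> float:
    """Mean resultant length R of a phase-difference distribution.

    Accepts a :class:`PhaseSyncResult` or a raw array of phase
    differences in degrees.  R = |mean exp(i dPhi)| in [0, 1]; it is 1
    minus the circular variance and invariant to rotating all angles.
    """
    if isinstance(result_or_pd, PhaseSyncResult):
        return float(np.abs(result_or_pd.unit_circle.mean()))
    pd_deg = np.asarray(result_or_pd, dtype=float)
    if pd_deg.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.mean(np.exp(1j * np.radians(pd_deg)))))


def population_phase_summary(results: Sequence[PhaseSyncResult],
                             ) -> PopulationPhaseSummary:
    """Circular mean across cells of the per-cell mean phase differences."""
    if len(results) == 0:
        raise ValueError("no per-cell results")
    per_cell = np.array([r.mean_pd for r in results])
    return PopulationPhaseSummary(
        mean_pd=circular_mean_deg(per_cell),
        pd_dispersion=circular_sd_deg(per_cell),
        n_cells=len(results),
        per_cell_pd=per_cell,
        per_cell_vectors=np.exp(1j * np.radians(per_cell)),
    )
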