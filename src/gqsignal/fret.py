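"""Ratiometric FRET and acceptor-photobleaching FRET summaries.

The FRET ratio is donor-channel emission divided by acceptor-emission
(FRET) channel under donor excitation — "donor/FRET" — so a loss of
energy transfer (donor dequenching) *increases* the ratio.  No spectral
bleed-through correction is applied.  For acceptor-photobleaching FRET
the ratio is averaged over a pre-bleach window (default 20 s, imaged at
1 Hz) and a post-bleach window (default 90 s) and reported as the
normalized difference (post - pre) / pre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .trace_io import TimeSeriesTrace

log = logging.getLogger(__name__)


class GridMismatchError(ValueError):
    """Donor and FRET channels are not on the same time grid."""


@dataclass
class FretResult:
    """Donor/FRET ratio series and window summaries."""

    time: np.ndarray
    ratio: np.ndarray
    n_excluded: int = 0
    pre_event_mean: float = float("nan")
    post_event_mean: float = float("nan")
    normalized_difference: float = float("nan")
    bleach_windows: tuple = ()


def fret_ratio(donor: TimeSeriesTrace, fret_channel: TimeSeriesTrace,
               floor_frac: float = 0.01,
               event_time: Optional[float] = None) -> FretResult:
    """Pointwise donor/FRET ratio.

    Samples where the FRET channel falls below ``floor_frac`` of its
    reference mean (pre-event mean if ``event_time`` is given, otherwise
    the channel mean) are excluded and counted.
    """
    if donor.time.size != fret_channel.time.size or not np.allclose(
            donor.time, fret_channel.time):
        raise GridMismatchError("donor and FRET traces on different grids")
    f = fret_channel.intensity
    if event_time is not None:
        pre = fret_channel.time < event_time
        ref = f[pre].mean() if pre.any() else f.mean()
    else:
        ref = f.mean()
    floor = floor_frac * ref
    valid = f > floor
    if not valid.any():
        raise ValueError("every FRET sample is below the intensity floor")
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("fret_ratio: excluded %d samples below floor", n_excluded)
    return FretResult(
        time=donor.time[valid].copy(),
        ratio=donor.intensity[valid] / f[valid],
        n_excluded=n_excluded,
    )


def photobleach_fret(donor: TimeSeriesTrace, fret_channel: TimeSeriesTrace,
                     bleach_time: float,
                     pre_window: float = 20.0,
                     post_window: float = 90.0) -> FretResult:
    """Acceptor-photobleaching FRET summary around ``bleach_time``.

    Mean donor/FRET ratio over [bleach - pre_window, bleach) and
    (bleach, bleach + post_window], with the normalized difference
    (post - pre) / pre.  A positive difference indicates donor
    dequenching, i.e. FRET was present before the bleach.
    """
    res = fret_ratio(donor, fret_channel, event_time=bleach_time)
    t, r = res.time, res.ratio
    pre_lo, post_hi = bleach_time - pre_window, bleach_time + post_window
    pre = (t >= pre_lo) & (t < bleach_time)
    post = (t > bleach_time) & (t <= post_hi)
    if not pre.any() or not post.any():
        raise ValueError("empty pre- or post-bleach window")
    pre_mean = float(r[pre].mean())
    post_mean = float(r[post].mean())
    return FretResult(
        time=t, ratio=r, n_excluded=res.n_excluded,
        pre_event_mean=pre_mean, post_event_mean=post_mean,
        normalized_difference=(post_mean - pre_mean) / pre_mean,
        bleach_windows=((float(pre_lo), float(bleach_time)),
                        (float(bleach_time), float(post_hi))),
    )
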