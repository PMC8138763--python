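"""Recovery-rate extraction and group statistics.

The adaptation/recovery rate of a response is the Hill slope ``p`` of a
dose-response sigmoid fitted to the recovery limb, with time playing the
role of the dose axis:

    F(t) = A1 + (A2 - A1) / (1 + 10**((t - t_mid) * p))      (falling limb)
    F(t) = A1 + (A2 - A1) / (1 + 10**((t_mid - t) * p))      (rising limb)

``p`` is in s^-1 and reported positive for both orientations; the base-10
exponent keeps fitted values numerically comparable across tools that use
the same pharmacology-style parameterization.  Group comparisons use
one-way ANOVA with Tukey's HSD at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .preprocess import AdaptationSeries, PMLossSeries
from .trace_io import TimeSeriesTrace


class ZeroVarianceError(ValueError):
    """The segment to fit (or compare) carries no signal variance."""


class GridMismatchError(ValueError):
    """Two series that must share a time grid do not."""


@dataclass
class HillFit:
    """Fitted dose-response sigmoid on the time axis.

    ``p`` (the Hill slope, s^-1) is the recovery/adaptation rate;
    ``t_mid`` is the midpoint time; ``a1``/``a2`` the lower/upper
    asymptotes in F/F0 units.
    """

    a1: float
    a2: float
    t_mid: float
    p: float
    residual_sse: float
    converged: bool
    n_points: int
    orientation: str = "falling"   # falling = recovering cytosolic signal


@dataclass
class RateComparison:
    """One-way ANOVA + Tukey HSD over named groups of per-cell slopes."""

    group_labels: list
    group_slopes: dict
    group_means: dict
    group_sds: dict
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey: list = field(default_factory=list)  # (g1, g2, diff, p_adj, reject)


@dataclass
class CouplingRegression:
    """OLS of adaptation% on PM loss% (slope, intercept, R^2, n)."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def _doseresp(t, a1, a2, t_mid, p, falling):
    expo = (t - t_mid) * p if falling else (t_mid - t) * p
    return a1 + (a2 - a1) / (1.0 + 10.0 ** expo)


def fit_dose_response(segment: TimeSeriesTrace,
                      window: Optional[Tuple[float, float]] = None,
                      n_restarts: int = 5) -> HillFit:
    """Least-squares fit of the dose-response sigmoid to a segment.

    Orientation (rising/falling limb) is auto-detected from the data;
    initialization is data-driven (asymptotes from the range, midpoint
    from the half-range crossing, slope from a coarse grid) with
    jittered restarts; the best SSE wins.  Non-convergence is flagged on
    the returned fit, never silent.
    """
    t, y = segment.time, segment.intensity
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    if t.size < 8:
        raise ValueError(f"need >= 8 samples in fit window, got {t.size}")
    if np.ptp(y) == 0:
        raise ZeroVarianceError("segment is constant; nothing to fit")

    t0 = t[0]
    ts = t - t0                       # shift for conditioning; restores below
    span = max(ts[-1], 1.0)
    q = max(2, t.size // 4)
    falling = y[:q].mean() > y[-q:].mean()

    ymin, ymax = float(y.min()), float(y.max())
    half = 0.5 * (ymin + ymax)
    cross = np.flatnonzero(np.diff(np.sign(y - half)) != 0)
    tm0 = float(ts[cross[0]]) if cross.size else float(0.5 * span)

    lower = np.array([ymin - np.ptp(y), ymin - np.ptp(y), -span, 1e-7])
    upper = np.array([ymax + np.ptp(y), ymax + np.ptp(y), 2 * span, 10.0])

    def residuals(theta):
        return _doseresp(ts, theta[0], theta[1], theta[2], theta[3], falling) - y

    # coarse grid on the slope picks the starting decade
    p_grid = np.array([3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1])
    sses = [float(np.sum(residuals([ymin, ymax, tm0, pg]) ** 2)) for pg in p_grid]
    p0 = float(p_grid[int(np.argmin(sses))])

    rng = np.random.default_rng(0)    # jitter only; fit is deterministic
    best = None
    for i in range(max(1, n_restarts)):
        if i == 0:
            x0 = np.array([ymin, ymax, tm0, p0])
        else:
            x0 = np.array([
                ymin + 0.1 * np.ptp(y) * rng.standard_normal(),
                ymax + 0.1 * np.ptp(y) * rng.standard_normal(),
                tm0 + 0.1 * span * rng.standard_normal(),
                p0 * np.exp(0.5 * rng.standard_normal()),
            ])
        x0 = np.clip(x0, lower, upper)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                         xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[0] - 1e-30:
            best = (sse, res)
    if best is None:
        raise RuntimeError("dose-response fit failed in every restart")
    sse, res = best
    a1, a2, tm, p = res.x
    if a2 < a1:                       # canonicalize: a2 is the upper asymptote
        a1, a2 = a2, a1
    return HillFit(a1=float(a1), a2=float(a2), t_mid=float(tm + t0),
                   p=float(p), residual_sse=sse,
                   converged=bool(res.success), n_points=int(t.size),
                   orientation="falling" if falling else "rising")


def estimate_half_time(trace: TimeSeriesTrace, event_time: float,
                       plateau_frac: float = 0.2,
                       plateau_tol: float = 0.05) -> float:
    """Half-time of the post-event transition, by linear interpolation.

    The post-event plateau is the mean of the trailing ``plateau_frac``
    of samples; it must be flat (net change across the trailing window
    below ``plateau_tol`` of the full response amplitude).  t_half is
    the first time the trace crosses the midpoint between its value at
    the event and the plateau, minus ``event_time``.
    """
    t, y = trace.time, trace.intensity
    post = t >= event_time
    if post.sum() < 4:
        raise ValueError("too few post-event samples")
    tp, yp = t[post], y[post]
    n_tail = max(2, int(np.ceil(plateau_frac * tp.size)))
    tail = yp[-n_tail:]
    pre_value = float(np.interp(event_time, t, y))
    plateau = float(tail.mean())
    amplitude = abs(plateau - pre_value)
    if amplitude == 0:
        raise ValueError("no post-event change; half-time undefined")
    if abs(float(tail[-1] - tail[0])) > plateau_tol * amplitude:
        raise ValueError("no post-event plateau detected")
    midpoint = 0.5 * (pre_value + plateau)
    sign = 1.0 if plateau > pre_value else -1.0
    above = sign * (yp - midpoint) >= 0
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise ValueError("trace never crosses the midpoint")
    i = idx[0]
    if i == 0:
        return float(tp[0] - event_time)
    # linear interpolation between the bracketing samples
    y0, y1 = yp[i - 1], yp[i]
    frac = (midpoint - y0) / (y1 - y0)
    t_cross = tp[i - 1] + frac * (tp[i] - tp[i - 1])
    return float(t_cross - event_time)


def correlate_adaptation_loss(adapt: AdaptationSeries,
                              loss: PMLossSeries,
                              min_points: int = 10) -> CouplingRegression:
    """OLS of adaptation% on loss% over the common time grid."""
    common, ia, il = np.intersect1d(adapt.time, loss.time,
                                    return_indices=True)
    if common.size < min_points:
        raise GridMismatchError(
            f"only {common.size} shared time points (need >= {min_points}); "
            "resample both series to a common grid first"
        )
    x = loss.loss_pct[il]
    y = adapt.adaptation_pct[ia]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant series; regression undefined")
    res = stats.linregress(x, y)
    return CouplingRegression(slope=float(res.slope),
                              intercept=float(res.intercept),
                              r_squared=float(res.rvalue ** 2),
                              n=int(common.size))


def compare_rates(groups: Dict[str, Sequence[float]],
                  alpha: float = 0.05) -> RateComparison:
    """One-way ANOVA over named slope groups, with Tukey HSD pairwise."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has < 2 members")
    labels = list(arrays)
    f_stat, p_value = stats.f_oneway(*arrays.values())
    n_total = sum(v.size for v in arrays.values())
    values = np.concatenate(list(arrays.values()))
    tags = np.concatenate([[k] * arrays[k].size for k in labels])
    tk = pairwise_tukeyhsd(values, tags, alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(tk.groupsunique, 2))
    tukey = [
        (str(g1), str(g2), float(diff), float(padj), bool(rej))
        for (g1, g2), diff, padj, rej in zip(
            pairs, tk.meandiffs, tk.pvalues, tk.reject)
    ]
    return RateComparison(
        group_labels=labels,
        group_slopes={k: v.tolist() for k, v in arrays.items()},
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sds={k: float(v.std(ddof=1)) for k, v in arrays.items()},
        f_stat=float(f_stat), df_between=len(labels) - 1,
        df_within=n_total - len(labels), p_value=float(p_value),
        tukey=tukey,
    )
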