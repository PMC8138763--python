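# Methods

## Scope and data model

The package analyzes single-cell fluorescence time series from
receptor-stimulation experiments in the Gq/PLCβ pathway.  Each trace is
one cell × sensor channel × compartment (plasma membrane, internal
membranes, or cytosol), in seconds and arbitrary intensity units,
nominally sampled at 2 Hz over 600–1500 s.  Perturbations (ligand
additions, a Gq inhibitor, blue-light on/off windows for an optogenetic
Gi/o-coupled receptor) live in a separate stimulus schedule so one
schedule serves a whole population of cells.

## The synthetic generator

No raw imaging data accompanies the phenomenon this pipeline targets,
so the generator is a first-class module: it produces populations of
traces with the kinetic structure of the real experiments, plus the
ground-truth parameters each cell was generated with, enabling
parameter-recovery tests at every stage.

It is deliberately *phenomenological*.  The underlying biology — a
Gαq–PLCβ–Gβγ complex whose βγ arm dissociates over time — has no
published rate equations, so the generator reproduces observable trace
shapes and printed rates rather than simulating mass action.

**PIP2 sensor (cytosolic PH domain).**  Baseline 1 before stimulus.  On
stimulation the trace rises exponentially toward the peak fold-change
`F_peak` at hydrolysis rate `k_h`, capped pointwise by the recovery
sigmoid

    F(t) = F_ss + (F_peak − F_ss) / (1 + 10^(p·(t − t_mid))),

so the trajectory is continuous, the realized peak is the crossover of
the two limbs (within a few percent of `F_peak`, never above it), and
the recovery limb is *exactly* the functional form the fitting stage
assumes — making noiseless parameter recovery an exact self-consistency
test.  An exponential-recovery mode exists to probe model mismatch.
Later events transform the current value: a second ligand re-elevates
toward `F_peak` and recovers more slowly to a higher plateau
(`second_f_ss`, `second_p`); a Gq inhibitor decays the trace to
baseline 1; a light-on window behaves like a hydrolysis episode with the
slow in-light slope; light-off starts a value-anchored sigmoid decay
with the fast post-light slope.

**Companion channels.**  The receptor-activity probe (mGq) saturates
exponentially at stimulus onset (fast, phase-locked with hydrolysis);
β-arrestin2 recruits along a normalized logistic with configurable
half-time; both are emitted in two orientations (PM recruitment rising,
cytosolic depletion falling).  The Gβ PM trace ramps to its at-peak loss
during hydrolysis and then moves linearly with the adaptation fraction:
loss%(t) = loss_peak + adaptation%(t)/m, so the noiseless regression of
adaptation% on loss% has slope `m` and R² = 1 by construction.  The Gγ
IM trace mirrors the PM loss.

**Defaults.**  The defaults are the study conditions: peak cytosolic
fold-change 2.60; steady-state plateau 1.80 (≈50% adaptation); recovery
Hill slope 1.27×10⁻² s⁻¹ with midpoint offset 184 s (the PIP2 recovery
half-time); second-episode slope 6.51×10⁻³ s⁻¹; in-light slope
2.55×10⁻³ s⁻¹ and post-light slope 1.60×10⁻² s⁻¹; arrestin half-time
738 s; maximum Gβγ PM loss 40%.  Values the source experiments do not
pin down were chosen once as plausible for this system and documented
here: hydrolysis rate k_h = 0.05 s⁻¹ (near-complete hydrolysis within
~1–2 min), inhibitor decay 0.03 s⁻¹ (full recovery in 2–3 min),
arrestin logistic time constant 150 s, mGq rate 0.05 s⁻¹, coupling
slope m = 2.5, Gγ presets "g9" (fast loss, 40%) vs "g3" (slow loss,
25%) differing only in loss rate and magnitude.

**Cell variability and noise.**  Per-cell kinetic parameters are drawn
as unit-mean lognormal multiples of the config means with a single
coefficient of variation (default 0.2); the response amplitude scales
`F_peak − 1` and its plateaus jointly so orderings are preserved.
Noise is multiplicative Gaussian (sd 0.02, the dominant
shot/expression term), additive Gaussian (sd 0.005), and an optional
linear bleach drift (default 0); negative samples are clipped at zero
and counted.  Everything is driven by one `numpy` Generator seeded from
the config, so identical (seed, config) gives byte-identical output.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: ROI segmentation error and motion,
photobleaching beyond a linear drift, sensor-buffering nonlinearity,
IP3/Ca²⁺ feedback dynamics, heterogeneous baselines within a cell, and
any mechanistic link between the Gβγ pool and the hydrolysis rate.  The
linear adaptation/loss coupling is imposed, not emergent; the R² ≈ 1
result on synthetic data validates the measurement chain, not the
biology.

## Analysis stages

**Normalization.**  Every sample is divided by the mean intensity over
the baseline window, by default [trace start, first scheduled event).
The averaging window is a package choice; the percent metrics downstream
are invariant to positive rescaling either way.

**Resampling.**  Natural cubic spline on a uniform grid inside the data
range (no extrapolation), requiring ≥ 4 knots.  Knot values are
reproduced exactly; traces sharing a span get identical grids.

**Percent adaptation.**  The peak is the first global extremum of
|F − 1| after the stimulus (search window ends at the next event by
default; ties break earliest).  For a cytosol-rising sensor,
adaptation% = 100·(F_peak − F)/(F_peak − 1); sign-mirrored for sensors
that fall on stimulation.  Values can exceed 100% on overshoot (e.g.
full recovery after Gq inhibition) and are reported unclipped with a
flag.  Percent PM loss is 100·(1 − F) against the preactivation level,
with transient negatives clipped and counted.

**Dose-response fitting.**  Nonlinear least squares (trust-region, with
bounds) of the base-10 sigmoid, orientation auto-detected from the
first-vs-last-quarter means.  Initialization is data-driven (asymptotes
from the range, midpoint from the half-range crossing, slope from a
coarse decade grid) with five jittered restarts; best SSE wins, ties to
the first.  Time is shifted to the segment origin for conditioning, so
fits are exactly invariant to time-origin shifts.  Non-convergence sets
a flag rather than raising.  Fit window default: post-stimulus peak to
the next scheduled event.

**Half-times.**  First crossing of the midpoint between the value at the
event and the trailing plateau (mean of the trailing 20% of post-event
samples, required flat to 5% of the response amplitude), located by
linear interpolation between samples.

**Group comparison.**  One-way ANOVA (`scipy.stats.f_oneway`) with
Tukey HSD pairwise at α = 0.05 (`statsmodels`); no further
multiple-testing correction.  For two groups, F equals the squared
two-sample t statistic — kept as an oracle identity in the tests.

**Phase synchronization.**  Traces are linearly detrended by default
(mean-only and raw modes available): the analytic-signal phase is
meaningful only for zero-mean signals.  Before the FFT-based Hilbert
transform, each trace is padded by 10% of its length using
*point-symmetric* (odd) reflection about its endpoints.  Plain mirror
reflection was rejected: reflecting a sinusoid reverses its phase
direction at the boundary and measurably distorts the interior envelope
(up to ~9%), whereas point reflection is continuous in value and slope
direction and leaves the interior of periodic signals essentially exact.
The outer 10% of samples at each end are flagged as edge-affected and
excluded from scalar summaries.

Phase differences are reported wrapped to [0°, 360°) by default; an
absolute [0°, 180°] folding is available behind a flag.  The wrapped
convention is the one under which slow, unsynchronized pairs can sit
near 350° rather than folding onto 10°.  All angle averaging is
circular (359° and 1° average to 0°); the circular SD is
√(−2 ln R) in degrees.  The phase coherence is the mean resultant
length R = |⟨e^{iΔΦ}⟩| — the standard phase-locking value, equal to one
minus the circular variance; the printed form of the coherence index in
the source material omits the averaging operator, and the mean resultant
length is the standard quantity consistent with "circular variance".

For pairing, both channels are resampled to the coarser of their native
rates over the overlapping span.  Synchrony comparisons between sensor
pairs use orientation-consistent traces (the PM recruitment signals
against the cytosolic PIP2 sensor); pairing a rising signal with its
inverted copy shifts the phase difference by 180° and is a choice the
caller controls through the channel/compartment selection.

**Coupling regression.**  Adaptation% regressed on loss% by OLS over
the shared grid.  The population-level regression defaults to the
cell-averaged curves (the presentation convention for this analysis,
where averaging suppresses measurement noise ~√n); a pooled per-sample
mode is provided.

**FRET.**  Donor/FRET ratio with an intensity floor at 1% of the FRET
channel's (pre-event) mean, excluded samples counted; acceptor
photobleaching uses a 20 s pre window and 90 s post window at 1 Hz by
default, reporting (post − pre)/pre.  No bleed-through correction.

## Numerical and edge-case conventions

Strictly increasing time and nonnegative intensities are enforced at
construction; duplicate or unsorted rows are rejected at ingest, naming
the offending trace.  Flat post-stimulus traces raise a "no response"
error rather than producing a 0/0 adaptation.  Constant segments raise
zero-variance errors in fitting, regression, and phase analysis.  The
circular mean guards the −0.0 → 360.0 float wrap.  Light on/off events
must strictly alternate per light source label.

## Problem sizes

The test suite and the acceptance script run simulations sized for a
single CPU: 20-cell populations at 2 Hz × 600–2000 s for end-to-end
checks, 3-cell populations across 50–100 seeds for ordering
frequencies, 50 fits per condition for recovery studies, and 500–1000
replicates for statistical calibration.  These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands.

## Known limitations

The generator's episode grammar covers the schedules used in the
emulated experiments (one or two stimulations, inhibition, light
windows) but not arbitrary overlapping perturbations.  The mGq and
arrestin channels do not respond to inhibitor events (their reversal
kinetics are not modeled).  The dose-response fit assumes a monotone
limb within the window; windows spanning a re-stimulation will produce
flagged, poor fits rather than errors.  Phase estimates on strongly
nonstationary signals remain convention-dependent near the edges even
with padding; only interior samples should be interpreted.
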