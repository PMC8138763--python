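# gqsignal

Analysis of single-cell fluorescence time series from Gq-coupled GPCR /
PLCβ signaling experiments: PIP2-hydrolysis adaptation kinetics, phase
synchronization between paired biosensor responses, the coupling of
hydrolysis adaptation to Gβγ loss from the plasma membrane, and FRET
ratios — plus a seeded synthetic-trace generator so the whole pipeline
is testable without microscopy data.

## The problem

Activating a Gq-coupled receptor triggers intense, near-complete
hydrolysis of the plasma-membrane lipid PIP2 by PLCβ, read out as
translocation of a PH-domain fluorescent sensor into the cytosol.  The
hydrolysis then *partially adapts*: the sensor signal relaxes from its
peak to a low-intensity steady state while the receptor stays active.
Quantifying that adaptation — its rate, its percentage, and which
co-measured molecular response it is synchronized with — is what this
package does, for tidy CSV/TSV tables of background-subtracted ROI
intensities (one row per `cell_id, channel, compartment, time_s,
intensity`) sampled at ~2 Hz, together with a JSON stimulus schedule
(ligand/inhibitor additions, blue-light optogenetic windows).

## Methods at the core

- **Adaptation rate** — each baseline-normalized (F/F₀) recovery limb is
  fitted with the pharmacology-style dose–response sigmoid on the time
  axis, `F(t) = A1 + (A2−A1) / (1 + 10^((t−t_mid)·p))`; the Hill slope
  `p` (s⁻¹) is the recovery/adaptation rate.  Groups of per-cell rates
  are compared by one-way ANOVA with Tukey HSD at α = 0.05.
- **Phase synchronization** — paired responses are spline-resampled to a
  common uniform grid, detrended, and given instantaneous phases via the
  Hilbert analytic signal.  The per-timepoint phase difference
  ΔΦ_p = Φ_x(t_p) − Φ_y(t_p) is wrapped to [0°, 360°) and summarized by
  its circular mean; the phase coherence R = |⟨e^{iΔΦ}⟩| (mean resultant
  length, 1 − circular variance) is the standard phase-locking value.
- **Percent metrics** — adaptation% is anchored at 0% at the
  post-stimulus extremum (maximum hydrolysis) and 100% at return to
  baseline; PM loss% is anchored at 0% at the preactivation level.
  Their linear coupling is quantified by OLS (slope, R²).
- **FRET** — donor/FRET ratio (donor emission ÷ acceptor-emission
  channel under donor excitation) and acceptor-photobleaching window
  summaries, `(post − pre)/pre`.
- **Synthetic data** — a phenomenological generator reproduces the
  study conditions (peak fold-change 2.60, recovery slope 1.27×10⁻²
  s⁻¹, slow arrestin recruitment t½ = 738 s, ~40% Gβγ PM loss linearly
  coupled to adaptation, optogenetic on/off switching) with per-cell
  lognormal variability and multiplicative + additive noise, all
  deterministic given a seed.

## Worked example

Simulate a 20-cell receptor-stimulation experiment and run the whole
analysis:

```sh
gqsignal --seed 1 --out-dir demo run-all
```

prints

```json
{
 "mean_recovery_slope_per_s": 0.011907738019343306,
 "mean_pd_pip2_mgq_deg": 24.53044850065279,
 "mean_pd_pip2_arrestin_deg": 242.6633103148372,
 "adaptation_loss_r_squared": 0.994320223113181,
 "n_cells": 20
}
```

Reading the numbers: the mean fitted recovery Hill slope (≈1.2×10⁻²
s⁻¹) is the population adaptation rate of PIP2 hydrolysis; the mean
phase difference between the PIP2 sensor and the fast receptor-activity
probe (mGq) is small (≈25°, strongly phase-locked), while the slow
β-arrestin2 pair sits far from zero (≈243°, weakly interdependent); and
the regression of percent adaptation on percent Gβγ PM loss is almost
perfectly linear (R² ≈ 0.99), the signature of adaptation being driven
by Gβγ leaving the membrane.

The same stages are available individually (`simulate`, `normalize`,
`fit-rates`, `phase-sync`, `adaptation`, `fret`) and as library
functions (`gqsignal.pipeline`, `gqsignal.kinetics`,
`gqsignal.phase_sync`, ...).

## Layout

```
src/gqsignal/
  trace_io.py     tidy trace tables, schedules, JSON results
  synthetic.py    seeded phenomenological trace generator
  preprocess.py   F/F0 normalization, spline resampling, percent metrics
  kinetics.py     dose-response fits, half-times, coupling, ANOVA/Tukey
  phase_sync.py   Hilbert phases, phase differences, phase-locking value
  fret.py         donor/FRET ratios and photobleach windows
  pipeline.py     orchestration helpers
  cli.py          command-line interface
docs/methods.md   model, assumptions, parameter choices, limitations
```
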