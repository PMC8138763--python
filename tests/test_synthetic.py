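"""Generator structure: determinism, trace shapes, and ground truth."""

import numpy as np
import pytest

from gqsignal import kinetics, pipeline, preprocess, synthetic
from gqsignal.synthetic import (
    ConfigError,
    GbgParams,
    NoiseParams,
    Pip2Params,
    SimulationConfig,
    simulate_population,
)
from gqsignal.trace_io import ScheduleError, StimulusEvent, StimulusSchedule

from conftest import NOISELESS


class TestConfigValidation:
    def test_rejects_bad_levels(self):
        with pytest.raises(ConfigError):
            Pip2Params(f_peak=1.5, f_ss=1.8).validate()
        with pytest.raises(ConfigError):
            Pip2Params(p=-1.0).validate()
        with pytest.raises(ConfigError):
            GbgParams(max_loss_pct=150.0).validate()
        with pytest.raises(ConfigError):
            NoiseParams(multiplicative_sd=-0.1).validate()

    def test_rejects_event_outside_duration(self):
        sched = StimulusSchedule(events=[StimulusEvent(900.0, "ligand_add", "x")])
        with pytest.raises(ScheduleError):
            SimulationConfig(duration=600.0, schedule=sched).validate()

    def test_rejects_unstimulated_schedule(self):
        cfg = SimulationConfig(schedule=StimulusSchedule(events=[]),
                               n_cells=1, cell_cv=0.0, noise=NOISELESS)
        with pytest.raises(ScheduleError):
            simulate_population(cfg)


class TestPip2Shape:
    def test_no_stimulus_before_event_is_baseline(self, noiseless_config):
        exp, _ = simulate_population(noiseless_config)
        t = exp.traces[0].time
        pre = exp.traces[0].intensity[t < 60.0]
        np.testing.assert_allclose(pre, noiseless_config.base_intensity)

    def test_noiseless_peak_approaches_configured_fold_change(self, noiseless_config):
        """The generated peak is the crossover of the hydrolysis rise and
        the recovery sigmoid: within a few % of F_peak, never above it."""
        exp, truth = simulate_population(noiseless_config)
        norm = pipeline.normalized(exp, "cell000", "PH", "cytosol")
        f_peak_cfg = truth.cells["cell000"].pip2.f_peak
        peak = norm.intensity.max()
        assert peak <= f_peak_cfg + 1e-12
        assert (f_peak_cfg - peak) / (f_peak_cfg - 1.0) < 0.03

    def test_recovery_segment_is_exact_sigmoid(self, noiseless_config):
        """Refitting the noiseless recovery limb returns the generating
        Hill slope to machine precision (residual < 1e-8)."""
        exp, truth = simulate_population(noiseless_config)
        fit = pipeline.recovery_fits(exp)["cell000"]
        p_true = truth.cells["cell000"].pip2.p
        assert abs(fit.p - p_true) / p_true < 1e-6
        assert fit.residual_sse < 1e-8

    def test_inhibitor_returns_trace_to_baseline(self):
        sched = StimulusSchedule(events=[
            StimulusEvent(60.0, "ligand_add", "bombesin"),
            StimulusEvent(400.0, "inhibitor_add", "YM-254890"),
        ])
        cfg = SimulationConfig(n_cells=1, duration=900.0, schedule=sched,
                               cell_cv=0.0, noise=NOISELESS)
        exp, _ = simulate_population(cfg)
        norm = pipeline.normalized(exp, "cell000", "PH", "cytosol")
        assert abs(norm.intensity[-1] - 1.0) < 1e-3

    def test_second_ligand_rehydrolyzes_to_higher_plateau(self):
        sched = StimulusSchedule(events=[
            StimulusEvent(60.0, "ligand_add", "carbachol"),
            StimulusEvent(600.0, "ligand_add", "bombesin"),
        ])
        cfg = SimulationConfig(n_cells=1, duration=1400.0, schedule=sched,
                               cell_cv=0.0, noise=NOISELESS)
        exp, truth = simulate_population(cfg)
        norm = pipeline.normalized(exp, "cell000", "PH", "cytosol")
        pp = truth.cells["cell000"].pip2
        t, f = norm.time, norm.intensity
        # re-elevation after the second addition
        assert f[t == 700.0] > f[t == 600.0]
        # the steady state after the second episode stays more hydrolyzed
        assert abs(f[-1] - pp.second_f_ss) < 0.05
        assert f[-1] > pp.f_ss

    def test_light_off_recovery_steeper_than_during_light(self, opto_schedule):
        """Slope ordering of the optogenetic experiment: recovery during
        continuous illumination is several-fold slower than after the
        light is switched off, in every noiseless run."""
        for seed in range(5):
            cfg = SimulationConfig(n_cells=1, duration=900.0,
                                   schedule=opto_schedule, cell_cv=0.0,
                                   noise=NOISELESS, seed=seed)
            exp, truth = simulate_population(cfg)
            norm = pipeline.normalized(exp, "cell000", "PH", "cytosol")
            adapt = preprocess.percent_adaptation(norm, 60.0)
            f_on = kinetics.fit_dose_response(norm, window=(adapt.t_peak, 360.0))
            f_off = kinetics.fit_dose_response(norm, window=(360.0, 900.0))
            assert f_off.p > f_on.p


class TestCompanions:
    def test_noiseless_adaptation_loss_coupling_is_exact(self, noiseless_config):
        exp, truth = simulate_population(noiseless_config)
        reg = pipeline.adaptation_loss_regression(exp, "cell000")
        assert reg.r_squared > 1 - 1e-9
        m = truth.cells["cell000"].gbg.coupling_m
        assert abs(reg.slope - m) / m < 1e-6

    def test_arrestin_half_rise_matches_configuration(self):
        cfg = SimulationConfig(n_cells=1, duration=2000.0, cell_cv=0.0,
                               noise=NOISELESS)
        exp, _ = simulate_population(cfg)
        norm = pipeline.normalized(exp, "cell000", "b-arrestin2", "cytosol")
        t_half = kinetics.estimate_half_time(norm, 60.0)
        assert abs(t_half - cfg.arrestin_t_half) < 5.0

    def test_gg_im_trace_mirrors_pm_loss(self, noiseless_config):
        exp, _ = simulate_population(noiseless_config)
        pm = pipeline.normalized(exp, "cell000", "Gb1", "PM")
        im = pipeline.normalized(exp, "cell000", "Gg9", "IM")
        np.testing.assert_allclose(im.intensity - 1.0, 1.0 - pm.intensity,
                                   atol=1e-9)

    def test_missing_pip2_trace_is_an_error(self, noiseless_config):
        cp = synthetic.draw_cell_params(noiseless_config,
                                        np.random.default_rng(0))
        with pytest.raises(ValueError):
            synthetic.simulate_companion_traces(noiseless_config, cp, None)


class TestPopulation:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_cells=10, seed=1, duration=120.0)
        paths = []
        for tag in ("a", "b"):
            exp, _ = simulate_population(cfg)
            p = tmp_path / f"{tag}.csv"
            from gqsignal.trace_io import write_experiment
            write_experiment(exp, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_zero_cv_gives_identical_cells(self):
        cfg = SimulationConfig(n_cells=5, cell_cv=0.0, noise=NOISELESS)
        exp, truth = simulate_population(cfg)
        slopes = truth.slopes()
        assert np.ptp(slopes) == 0
        ref = exp.get("cell000", "PH", "cytosol").intensity
        for i in range(1, 5):
            np.testing.assert_array_equal(
                exp.get(f"cell{i:03d}", "PH", "cytosol").intensity, ref)

    def test_realized_slope_cv_tracks_configured_cv(self):
        cfg = SimulationConfig(n_cells=200, cell_cv=0.2, noise=NOISELESS,
                               duration=10.0,
                               schedule=StimulusSchedule(events=[
                                   StimulusEvent(1.0, "ligand_add", "x")]),
                               seed=5)
        _, truth = simulate_population(cfg)
        slopes = truth.slopes()
        cv = slopes.std(ddof=1) / slopes.mean()
        assert abs(cv - 0.2) / 0.2 < 0.25

    def test_intensities_nonnegative_under_heavy_noise(self):
        cfg = SimulationConfig(n_cells=3, seed=2,
                               noise=NoiseParams(0.5, 0.5, 0.1))
        exp, _ = simulate_population(cfg)
        for tr in exp.traces:
            assert np.all(tr.intensity >= 0)
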