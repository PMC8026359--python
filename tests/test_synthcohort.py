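"""Statistical structure and determinism of the synthetic-cohort generator."""

import dataclasses

import numpy as np
import pytest

from knobmap.config import GeneratorConfig
from knobmap.errors import ConfigError
from knobmap.synthcohort import (default_grid, serialize_cohort,
                                 simulate_cohort, simulate_emg_session,
                                 simulate_force_trace, simulate_subject,
                                 site_amplitude_surface, _rng)
from knobmap.timing import analyze_force_trace


def noise_free_config(**kw):
    base = GeneratorConfig()
    return dataclasses.replace(
        base,
        r1_caudal_sd=1.0, r1_rostral_sd=1.0, r1_diff_sd=0.0,
        thickness_caudal_sd=1.0, thickness_rostral_sd=1.0, thickness_diff_sd=0.0,
        bold_caudal_sd=1.0, bold_rostral_sd=1.0, bold_diff_sd=0.0,
        curvature_sd=1.0, curvature_diff_sd=0.0,
        latency_resid_sd_fdi=0.0, latency_resid_sd_adm=0.0,
        x_sd_fdi=0.0, x_sd_adm=0.0,
        rho_r1_rostrality=1.0, rho_adm_coupling=1.0,
        rho_r1_bold_index=1.0, rho_r1_bold_little=1.0,
        rho_r1_cv_index=-1.0, rho_r1_cv_little=-1.0,
        mep_amp_subject_sd_fdi=0.0, mep_amp_subject_sd_adm=0.0,
        rmt_sd=0.0,
        **kw)


class TestLatentTraitModel:
    def test_noise_free_fields_are_linear_in_latent(self):
        """With unit loadings and zero residuals every field is an exact
        linear (deterministic) function of the latent myelin trait."""
        cfg = noise_free_config()
        subs = [simulate_subject(cfg, i) for i in range(40)]
        z = np.array([s.latent_myelin for s in subs])
        for getter in [lambda s: s.r1_mean,
                       lambda s: s.true_hotspot["FDI"][1],
                       lambda s: s.true_latency["FDI"],
                       lambda s: s.bold_little,
                       lambda s: s.cv_little]:
            v = np.array([getter(s) for s in subs])
            r = np.corrcoef(z, v)[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_r1_caudal_mean_matches_calibration(self, config):
        vals = [simulate_subject(config, i).roi_r1_caudal for i in range(10_000)]
        assert np.mean(vals) == pytest.approx(796.48, abs=1.0)

    def test_copula_correlation_matches_loading(self, config):
        """Sample corr(mean R1, rostrality driver) ≈ rho_r1_rostrality.

        The driver is recovered from the anterior-posterior hotspot position,
        which is an exact linear function of it.
        """
        subs = [simulate_subject(config, i) for i in range(10_000)]
        r1 = np.array([s.r1_mean for s in subs])
        driver = np.array([s.true_hotspot["FDI"][1] for s in subs])
        r = np.corrcoef(r1, driver)[0, 1]
        assert r == pytest.approx(config.rho_r1_rostrality, abs=0.03)

    def test_gradient_direction(self, config):
        subs = [simulate_subject(config, i) for i in range(200)]
        caudal = np.mean([s.roi_r1_caudal for s in subs])
        rostral = np.mean([s.roi_r1_rostral for s in subs])
        assert caudal > rostral

    def test_cv_nonnegative(self, config):
        subs = [simulate_subject(config, i) for i in range(500)]
        assert all(s.cv_index > 0 and s.cv_little > 0 for s in subs)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(rho_r1_rostrality=1.5).validate()
        with pytest.raises(ConfigError):
            GeneratorConfig(n_subjects=2).validate()
        with pytest.raises(ConfigError):
            GeneratorConfig(trial_amp_cv=-0.1).validate()
        with pytest.raises(ConfigError):
            # ROI difference more variable than the marginals allow -> not PSD
            GeneratorConfig(r1_diff_sd=500.0).validate()


class TestEMGSession:
    def test_noise_free_site_means_equal_gaussian_surface(self, knob_grid):
        cfg = dataclasses.replace(GeneratorConfig(), emg_noise_sd=0.0,
                                  trial_amp_cv=0.0, trial_latency_jitter_sd=0.0)
        subj = simulate_subject(cfg, 7)
        traces = simulate_emg_session(subj, knob_grid, cfg, _rng(0, 7, 1),
                                      muscles=("FDI",), dtype=np.float64)["FDI"]
        amps = traces[..., 1100:1401].max(-1) - traces[..., 1100:1401].min(-1)
        surf = site_amplitude_surface(subj, knob_grid, cfg, "FDI")
        assert np.allclose(amps.mean(axis=1), surf, atol=1e-12)

    def test_hotspot_site_wins_in_most_sessions(self, config, knob_grid):
        """At default noise the site nearest the true hotspot should carry
        the largest mean amplitude in ≥ 99% of sessions (site level)."""
        from knobmap.synthcohort import simulate_site_trials
        wins = 0
        n = 300
        for i in range(n):
            subj = simulate_subject(config, i)
            # park the hotspot exactly on a mid-grid site for a clean oracle
            subj.true_hotspot["FDI"] = tuple(knob_grid.positions[2, 3, :2])
            amps, _ = simulate_site_trials(subj, knob_grid, config, "FDI",
                                           _rng(1, i, 5))
            wins += int(np.argmax(amps.mean(axis=1)) == 2 * 7 + 3)
        assert wins / n >= 0.99

    def test_artifact_injection_rate(self, knob_grid):
        cfg = dataclasses.replace(GeneratorConfig(), artifact_rate=0.2)
        subj = simulate_subject(cfg, 0)
        traces = simulate_emg_session(subj, knob_grid, cfg, _rng(0, 0, 1),
                                      muscles=("FDI",))["FDI"]
        rms = np.sqrt((traces[..., :1000] ** 2).mean(-1))
        frac = (rms > 0.02).mean()
        assert frac == pytest.approx(0.2, abs=0.05)


class TestForceTrace:
    def test_zero_cv_gives_exact_one_second_intervals(self, config):
        ft = simulate_force_trace(0.0, dataclasses.replace(config, force_noise_sd=0.0),
                                  _rng(0, 0, 2))
        res = analyze_force_trace(ft)
        assert np.allclose(res.intervals, 1.0, atol=2.5e-3)  # one 500 Hz sample

    def test_recovered_cv_tracks_target(self, config):
        cvs = []
        for i in range(500):
            ft = simulate_force_trace(0.05, config, _rng(3, i, 2))
            cvs.append(analyze_force_trace(ft).cv)
        assert np.mean(cvs) == pytest.approx(0.05, abs=0.005)

    def test_clipping_at_sensor_ceiling(self, config):
        cfg = dataclasses.replace(config, pulse_amp_mean=3.0, pulse_amp_cv=0.0,
                                  force_noise_sd=0.0)
        ft = simulate_force_trace(0.02, cfg, _rng(0, 1, 2))
        assert ft.samples.max() == pytest.approx(2.5)
        assert ft.samples.min() >= 0.0

    def test_negative_cv_rejected(self, config):
        with pytest.raises(ConfigError):
            simulate_force_trace(-0.1, config, _rng(0, 0, 2))


class TestCohort:
    def test_cohort_shape_and_sessions(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=24)
        cohort = simulate_cohort(cfg, level="emg", with_force=False)
        assert len(cohort.table) == 24
        assert set(cohort.emg) == set(range(24))
        for sid in (0, 23):
            for muscle in ("FDI", "ADM"):
                assert cohort.emg[sid][muscle].shape == (35, 20, 1600)

    def test_identical_seeds_bitwise_identical(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=4, seed=99)
        a = serialize_cohort(simulate_cohort(cfg, level="site"))
        b = serialize_cohort(simulate_cohort(cfg, level="site"))
        assert a == b

    def test_different_seeds_differ(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=4, seed=99)
        cfg2 = dataclasses.replace(cfg, seed=100)
        a = serialize_cohort(simulate_cohort(cfg, level="site"))
        b = serialize_cohort(simulate_cohort(cfg2, level="site"))
        assert a != b

    def test_adding_subjects_preserves_existing(self):
        small = simulate_cohort(dataclasses.replace(GeneratorConfig(), n_subjects=5,
                                                    seed=7), level="table")
        large = simulate_cohort(dataclasses.replace(GeneratorConfig(), n_subjects=8,
                                                    seed=7), level="table")
        assert small.table.equals(large.table.iloc[:5].reset_index(drop=True))

    def test_write_cohort_manifest_links_subject_files(self, tmp_path):
        from knobmap.synthcohort import write_cohort
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=3, seed=4)
        cohort = simulate_cohort(cfg, level="site", force_fingers=("little",))
        manifest = write_cohort(cohort, tmp_path)
        assert set(manifest["subjects"]) == {0, 1, 2}
        fname = manifest["subjects"][0]["force_little"]
        df = __import__("pandas").read_csv(tmp_path / fname)
        assert list(df.columns) == ["time", "volts"]
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "cohort.csv").exists()

    def test_r1_missing_subjects(self):
        cfg = dataclasses.replace(GeneratorConfig(), n_subjects=24, r1_missing=4)
        cohort = simulate_cohort(cfg, level="table")
        assert cohort.table["r1_mean"].isna().sum() == 4
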