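import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from stancelab.errors import ConfigError, GenerationError
from stancelab.footkin import check_orthonormal, jcs_angles
from stancelab.outcomes import GRAVITY
from stancelab.synthgait import (CohortConfig, EffectCell, default_effect_table,
                                 default_joint_programs, generate_cohort,
                                 read_cohort, simulate_outcome_table, synth_grf,
                                 synth_segment_poses, write_cohort)
from tests.conftest import zero_noise_config


class TestConfig:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_per_group=(1, 5)), "n_per_group"),
        (dict(kin_rate=0), "kin_rate"),
        (dict(noise_sd_marker=-1), "noise_sd_marker"),
        (dict(stance_duration_s=0.2501), "stance_duration_s"),
    ])
    def test_invalid_field_named_in_error(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            CohortConfig(**kwargs)

    def test_unknown_outcome_rejected(self):
        table = {"bogus": EffectCell(1, 1, 1, 1, 0.5)}
        with pytest.raises(ConfigError, match="bogus"):
            CohortConfig(effect_table=table)


class TestSynthGRF:
    def test_planted_impact_peak_in_newtons(self):
        # 1.14 BW at 70.5 kg -> early-stance local maximum of 1.14 * m * g
        g = synth_grf(0.25, 70.5, 1.14, 2.4, 75.0, -0.24, 1000.0)
        early = g.grf_v[g.contact_index:g.contact_index + 75]
        k = np.flatnonzero((early[1:-1] > early[:-2]) & (early[1:-1] >= early[2:]))
        assert early[k[0] + 1] == pytest.approx(1.14 * 70.5 * GRAVITY, rel=1e-12)

    def test_planted_braking_minimum_in_newtons(self):
        mass = 700.0 / GRAVITY  # BW exactly 700 N
        g = synth_grf(0.25, mass, 1.14, 2.4, 75.0, -0.24, 1000.0)
        assert g.grf_ap.min() == pytest.approx(-168.0, rel=1e-12)

    def test_threshold_crossed_once_up_once_down(self):
        g = synth_grf(0.25, 70.0, 1.2, 2.4, 80.0, -0.2, 1000.0)
        above = (g.grf_v >= 30.0).astype(int)
        assert (np.diff(above) == 1).sum() == 1
        assert (np.diff(above) == -1).sum() == 1

    def test_unreachable_constraints_raise(self):
        with pytest.raises(GenerationError):
            synth_grf(0.25, 70.0, 2.5, 2.4, 75.0, -0.24, 1000.0)  # impact >= active
        with pytest.raises(GenerationError):
            synth_grf(0.25, 70.0, 1.2, 2.4, 75.0, 0.1, 1000.0)    # braking > 0
        with pytest.raises(GenerationError):
            synth_grf(0.25, 70.0, 1.2, 2.4, 1e4, -0.2, 1000.0)    # rise too steep


class TestPoses:
    def test_zero_programs_give_identity_rotations(self):
        zero = lambda f: np.zeros_like(f)
        progs = {j: {"sagittal": zero, "frontal": zero, "transverse": zero}
                 for j in ("Sha-Cal", "Cal-Mid", "Mid-Met", "Met-Hal")}
        poses, _ = synth_segment_poses(progs, 200.0, 0.25)
        for seg, (R, _) in poses.items():
            assert np.allclose(R, np.eye(3), atol=1e-14), seg

    def test_rotations_orthonormal(self, noisy_cohort):
        cohort, _ = noisy_cohort
        for trial in cohort.trials[:4]:
            for seg, (R, _) in trial.segment_poses.items():
                check_orthonormal(R, tol=1e-9)

    def test_constant_frontal_program_recovered_everywhere(self):
        rng = np.random.default_rng(0)
        progs = default_joint_programs(rng, 0.0,
                                       shacal_frontal=lambda f: np.full_like(f, -5.74))
        poses, _ = synth_segment_poses(progs, 200.0, 0.25)
        ja = jcs_angles(poses["shank"][0], poses["calcaneus"][0])
        assert np.allclose(ja.frontal, -5.74, atol=1e-9)

    def test_random_program_round_trip(self, rng):
        # composing poses and decomposing with the JCS module recovers the
        # programs to numerical precision
        for _ in range(20):
            progs = default_joint_programs(np.random.default_rng(rng.integers(2**31)), 2.0)
            poses, _ = synth_segment_poses(progs, 200.0, 0.25)
            frac = np.arange(51) / 50.0
            for joint, (prox, dist) in {"Sha-Cal": ("shank", "calcaneus"),
                                        "Cal-Mid": ("calcaneus", "midfoot"),
                                        "Mid-Met": ("midfoot", "metatarsus"),
                                        "Met-Hal": ("metatarsus", "hallux")}.items():
                ja = jcs_angles(poses[prox][0], poses[dist][0])
                for plane in ("sagittal", "frontal", "transverse"):
                    want = progs[joint][plane](frac)
                    assert np.abs(ja.plane(plane) - want).max() < 1e-6

    def test_gimbal_proximity_raises(self):
        zero = lambda f: np.zeros_like(f)
        big = lambda f: np.full_like(f, 90.5)
        progs = {j: {"sagittal": zero, "frontal": zero, "transverse": zero}
                 for j in ("Sha-Cal", "Cal-Mid", "Mid-Met", "Met-Hal")}
        progs["Cal-Mid"]["frontal"] = big
        with pytest.raises(GenerationError):
            synth_segment_poses(progs, 200.0, 0.25)


class TestCohort:
    def test_zero_noise_planted_values_equal_cell_means(self, zero_noise_cohort):
        cohort, cfg = zero_noise_cohort
        for trial in cohort.trials:
            for name, cell in cfg.effect_table.items():
                assert trial.planted[name] == cell.means()[(trial.group, trial.time)]

    def test_true_events_match_series(self, noisy_cohort):
        cohort, _ = noisy_cohort
        for trial in cohort.trials[:6]:
            c, t = trial.true_events
            assert trial.grf_v[c] >= 30.0 > trial.grf_v[c - 1]
            assert trial.grf_v[t] >= 30.0 > trial.grf_v[t + 1]

    def test_seeded_generation_is_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_per_group=(2, 2), seed=77)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(CohortConfig(n_per_group=(2, 2), seed=77)), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert mismatch == [] and errors == []

    def test_roundtrip_through_csv(self, tmp_path):
        cfg = zero_noise_config()
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back.trials) == len(cohort.trials)
        t0, t1 = cohort.trials[0], back.trials[0]
        assert np.allclose(t0.grf_v, t1.grf_v)
        assert np.allclose(t0.segment_poses["hallux"][0], t1.segment_poses["hallux"][0])
        assert np.allclose(t0.markers["arch_apex"], t1.markers["arch_apex"])

    def test_statistical_faithfulness_at_large_n(self):
        # sample means of planted outcomes within 3 SE of configured means
        cfg = CohortConfig(n_per_group=(500, 500), seed=9)
        df = simulate_outcome_table(cfg)
        for name, cell in cfg.effect_table.items():
            for (grp, tim), mean in cell.means().items():
                sd = cell.sds()[(grp, tim)]
                vals = df[(df.outcome == name) & (df.group == grp)
                          & (df.time == tim)].value
                se = sd / np.sqrt(len(vals))
                assert abs(vals.mean() - mean) < 3 * se, (name, grp, tim)

    def test_difference_in_differences_of_planted_mla(self):
        cfg = CohortConfig(n_per_group=(2000, 2000), seed=4)
        df = simulate_outcome_table(cfg)
        m = df[df.outcome == "mla_rom"].groupby(["group", "time"]).value.mean()
        did = (m["IG", "week8"] - m["IG", "baseline"]) \
            - (m["CG", "week8"] - m["CG", "baseline"])
        assert did == pytest.approx(-5.28, abs=0.7)
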