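"""Synthetic session generator: determinism, null cases, ground truth."""

import numpy as np
import pytest

from mepkit.core_io import validate_session
from mepkit.synthetic import (
    Animal,
    SimConfig,
    band_limited_noise,
    default_group_profiles,
    flat_group_profiles,
    make_animals,
    mep_envelope,
    simulate_cohort,
    simulate_mep_session,
    simulate_mn_counts,
    simulate_mvc_session,
    simulate_recruitment_series,
    small_config,
)


class TestDeterminism:
    def test_mep_sessions_bit_identical_for_fixed_seed(self, quick_cfg, animal):
        a = simulate_mep_session(quick_cfg, animal, 1, 2.25, seed=11)
        b = simulate_mep_session(quick_cfg, animal, 1, 2.25, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)
        np.testing.assert_array_equal(a.stim_events, b.stim_events)

    def test_mvc_sessions_bit_identical_for_fixed_seed(self, quick_cfg, animal):
        a = simulate_mvc_session(quick_cfg, animal, 4, seed=11)
        b = simulate_mvc_session(quick_cfg, animal, 4, seed=11)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert [t.grip_force for t in a.trial_events] == [
            t.grip_force for t in b.trial_events
        ]

    def test_different_seeds_differ(self, quick_cfg, animal):
        a = simulate_mep_session(quick_cfg, animal, 1, 2.25, seed=11)
        b = simulate_mep_session(quick_cfg, animal, 1, 2.25, seed=12)
        assert not np.array_equal(a.signal, b.signal)

    def test_recruitment_series_deterministic(self, quick_cfg, animal):
        s1 = simulate_recruitment_series(quick_cfg, animal, seed=5)
        s2 = simulate_recruitment_series(quick_cfg, animal, seed=5)
        for (c1, a), (c2, b) in zip(s1, s2):
            assert c1 == c2
            np.testing.assert_array_equal(a.signal, b.signal)

    def test_mn_counts_deterministic(self):
        means = {"naive": {lv: 50.0 for lv in ("C5", "C6", "C7")}}
        a = simulate_mn_counts(4, means, dispersion=0.2, seed=3)
        b = simulate_mn_counts(4, means, dispersion=0.2, seed=3)
        assert a.equals(b)


class TestMEPSessions:
    def test_session_structure(self, quick_cfg, animal):
        s = simulate_mep_session(quick_cfg, animal, -1, 2.25, seed=0)
        assert validate_session(s) == []
        assert len(s.stim_events) == quick_cfg.n_triggers
        isis = np.diff(s.stim_events)
        np.testing.assert_allclose(isis, quick_cfg.isi_s)

    def test_unknown_week_rejected(self, quick_cfg, animal):
        with pytest.raises(ValueError, match="week"):
            simulate_mep_session(quick_cfg, animal, 99, 2.25, seed=0)

    def test_subthreshold_current_produces_no_burst(self, noiseless_cfg, animal):
        s = simulate_mep_session(noiseless_cfg, animal, -1, 1.0, seed=0)
        assert not s.extras["truth"]["suprathreshold"]
        # away from the brief stimulus artifacts the trace is silent
        x = np.abs(s.signal[0])
        assert np.median(x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_amp_multiplier_leaves_post_windows_at_background(self, animal):
        cfg = small_config(
            group_profiles={
                g: {w: 0.0 for w in (-1, 1, 4, 6, 11)}
                for g in ("untreated", "chabc_only", "triple")
            },
            artifact_rate_hz=0.0,
        )
        s = simulate_mep_session(cfg, animal, 1, 2.25, seed=0)
        fs = cfg.fs
        pre_rms, post_rms = [], []
        for t_ev in s.stim_events:
            i = int(round(t_ev * fs))
            pre_rms.append(np.sqrt(np.mean(s.signal[0, i - 400 : i - 40] ** 2)))
            post_rms.append(np.sqrt(np.mean(s.signal[0, i + 40 : i + 400] ** 2)))
        # same RMS distribution before and after the stimulus
        assert np.mean(post_rms) == pytest.approx(np.mean(pre_rms), rel=0.05)

    def test_burst_amplitude_scales_with_current_up_to_cap(self, noiseless_cfg, animal):
        s1 = simulate_mep_session(noiseless_cfg, animal, -1, 1.5, seed=0)
        s2 = simulate_mep_session(noiseless_cfg, animal, -1, 2.25, seed=0)
        assert s2.extras["truth"]["amp_eff_mV"] == pytest.approx(
            1.5 * s1.extras["truth"]["amp_eff_mV"]
        )

    def test_envelope_peaks_where_configured(self):
        t = np.linspace(0.0, 80.0, 8001)
        env = mep_envelope(t, latency_ms=8.0, dur_ms=15.0, shape_k=4.0)
        assert env.max() == pytest.approx(1.0, abs=1e-6)
        assert t[env.argmax()] == pytest.approx(8.0 + 15.0 / 4.0, abs=0.05)
        assert env[t < 8.0].max() == 0.0


class TestMVCSessions:
    def test_trial_layout(self, quick_cfg, animal):
        s = simulate_mvc_session(quick_cfg, animal, 4, seed=0)
        assert validate_session(s) == []
        assert len(s.trial_events) == 2 * quick_cfg.n_trials_per_limb
        limbs = [t.limb for t in s.trial_events]
        assert limbs.count("R") == limbs.count("L") == quick_cfg.n_trials_per_limb
        for tr in s.trial_events:
            assert tr.duration_s == pytest.approx(quick_cfg.mvc_trial_s)

    def test_zero_multiplier_trial_matches_background_auc(self, animal):
        cfg = small_config(
            group_profiles={
                g: {w: 0.0 for w in (-1, 1, 4, 6, 11)}
                for g in ("untreated", "chabc_only", "triple")
            },
            artifact_rate_hz=0.0,
        )
        s = simulate_mvc_session(cfg, animal, 1, seed=0)
        fs = cfg.fs
        tr = s.trial_events[0]
        inside = np.abs(
            s.signal[0, int(tr.start_s * fs) : int(tr.end_s * fs)]
        ).mean()
        gap = np.abs(
            s.signal[0, int((tr.end_s + 0.1) * fs) : int((tr.end_s + 0.4) * fs)]
        ).mean()
        assert inside == pytest.approx(gap, rel=0.1)

    def test_doubling_amplitude_doubles_excess_rectified_mean(self, animal):
        # with no background, mean |signal| inside the burst is proportional
        # to the configured amplitude (closed form of the burst model)
        means = []
        for amp in (0.5, 1.0):
            cfg = small_config(bg_rms_mV=0.0, artifact_rate_hz=0.0, mvc_amp_mV=amp)
            s = simulate_mvc_session(cfg, animal, -1, seed=4)
            tr = s.trial_events[0]
            i0, i1 = int(tr.start_s * cfg.fs), int(tr.end_s * cfg.fs)
            means.append(np.abs(s.signal[0, i0:i1]).mean())
        assert means[1] == pytest.approx(2.0 * means[0], rel=1e-9)

    def test_grip_force_only_weakly_coupled_to_emg_effect(self, animal):
        cfg = small_config()
        strong = Animal("a", "triple", 1.5, 1.0)
        weak = Animal("b", "untreated", 1.5, 1.0)
        g_strong = np.mean(
            [t.grip_force for t in simulate_mvc_session(cfg, strong, 11, seed=1).trial_events]
        )
        g_weak = np.mean(
            [t.grip_force for t in simulate_mvc_session(cfg, weak, 11, seed=1).trial_events]
        )
        # EMG multipliers differ 3x, grip means differ only a few percent
        assert abs(g_strong / g_weak - 1.0) < 0.25


class TestRecruitment:
    def test_sessions_split_at_the_configured_threshold(self, quick_cfg, animal):
        series = simulate_recruitment_series(quick_cfg, animal, seed=2)
        for current, session in series:
            assert session.extras["truth"]["suprathreshold"] == (
                current >= animal.threshold_mA
            )

    def test_truth_above_grid_yields_all_subthreshold(self, quick_cfg):
        high = Animal("hi", "untreated", threshold_mA=99.0)
        series = simulate_recruitment_series(quick_cfg, high, seed=2)
        assert not any(s.extras["truth"]["suprathreshold"] for _, s in series)

    def test_empty_grid_rejected(self, animal):
        cfg = small_config(current_grid=())
        with pytest.raises(ValueError, match="grid"):
            simulate_recruitment_series(cfg, animal, seed=0)


class TestCohort:
    def test_manifest_covers_full_factorial(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, seed=0)
        m = cohort.manifest
        assert len(m) == 3 * cfg.n_animals * len(cfg.weeks) * 2
        assert set(m["modality"]) == {"mep", "mvc"}
        per_animal = m.groupby("animal_id").size()
        assert per_animal.eq(len(cfg.weeks) * 2).all()

    def test_truth_table_contains_multipliers_and_expected_aucs(self):
        cfg = small_config()
        cohort = simulate_cohort(cfg, seed=0)
        measures = set(cohort.truth["measure"])
        assert {"multiplier", "animal_factor", "true_mep_auc_mVms", "true_mvc_auc_mVms"} <= measures

    def test_sessions_reproducible_and_consistent_with_manifest(self):
        cfg = small_config(n_animals=1, weeks=(-1, 1))
        a = simulate_cohort(cfg, seed=3)
        b = simulate_cohort(cfg, seed=3)
        sa = a.build(0)
        sb = b.build(0)
        np.testing.assert_array_equal(sa.signal, sb.signal)
        row = a.manifest.iloc[0]
        assert sa.animal_id == row["animal_id"] and sa.week == row["week"]

    def test_animal_factors_are_positive_and_stable(self):
        cfg = small_config()
        animals = make_animals(cfg, seed=1)
        again = make_animals(cfg, seed=1)
        assert all(a.factor > 0 for a in animals)
        assert [a.factor for a in animals] == [a.factor for a in again]

    def test_profiles_default_and_flat(self):
        weeks = (-1, 1, 4, 5, 6, 11)
        groups = ("untreated", "triple")
        prof = default_group_profiles(groups, weeks)
        flat = flat_group_profiles(groups, weeks)
        assert prof["triple"][-1] == 1.0  # intact at baseline
        assert prof["triple"][1] < prof["triple"][4] < prof["triple"][6]  # rise from wk 4
        assert prof["triple"][6] == prof["triple"][11]  # plateau
        assert prof["untreated"][11] < prof["triple"][11]
        assert all(v == 1.0 for g in flat.values() for v in g.values())


class TestMNCounts:
    LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7", "C8", "T1", "T2")

    def test_zero_means_give_zero_counts(self):
        means = {"naive": {lv: 0.0 for lv in self.LEVELS}}
        out = simulate_mn_counts(5, means, dispersion=0.3, seed=0)
        assert (out["count"] == 0).all()

    def test_sample_means_approach_configured_means(self):
        from mepkit.mn_mapping import load_reference_counts, summarize_counts

        ref = summarize_counts(load_reference_counts()).per_level
        naive = ref[ref["group"] == "naive"].set_index("level")
        means = {"naive": {lv: float(naive.loc[lv, "mean"]) for lv in self.LEVELS}}
        n = 200
        out = simulate_mn_counts(n, means, dispersion=0.15, seed=1)
        got = out.groupby("level", observed=True)["count"].mean()
        for lv in self.LEVELS:
            mu = means["naive"][lv]
            if mu == 0:
                assert got[lv] == 0
            else:
                se = np.sqrt((mu + 0.15 * mu**2) / n)
                assert abs(got[lv] - mu) < 3 * se

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            simulate_mn_counts(3, {"naive": {"C5": -1.0}}, dispersion=0.1, seed=0)


class TestBandNoise:
    def test_exact_rms_and_band_concentration(self, rng):
        fs, n = 8000.0, 40_000
        x = band_limited_noise(rng, n, fs, (100.0, 1000.0), rms=0.05)
        assert np.std(x) == pytest.approx(0.05, rel=1e-9)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        power = np.abs(np.fft.rfft(x)) ** 2
        in_band = power[(freqs > 80) & (freqs < 1200)].sum()
        assert in_band / power.sum() > 0.95

    def test_zero_rms_returns_silence(self, rng):
        assert not band_limited_noise(rng, 100, 8000.0, (100.0, 1000.0), 0.0).any()
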