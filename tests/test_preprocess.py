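import numpy as np
import pytest

from alphalat import (
    apply_rejection_cascade,
    downsample,
    generate_dataset,
    inject_artifacts,
    make_sensor_array,
    reject_gaze,
    reject_power_outliers,
    reject_rt,
    segment_demean_filter,
    to_planar_gradient,
)
from alphalat.layout import SensorArray
from alphalat import GeneratorConfig

from conftest import make_subject


class TestDownsample:
    def test_sample_count_scales_by_ratio(self, rng):
        x = rng.standard_normal(1200)
        assert downsample(x, 1200, 300).shape == (300,)

    def test_passband_tone_amplitude_preserved(self):
        t = np.arange(4800) / 1200.0
        x = np.sin(2 * np.pi * 10 * t)
        y = downsample(x, 1200, 300)
        # compare against the analytically sampled sinusoid (skip filter edges)
        ref = np.sin(2 * np.pi * 10 * np.arange(1200) / 300.0)
        core = slice(100, -100)
        assert np.max(np.abs(y[core] - ref[core])) < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(4800) / 1200.0
        x = np.sin(2 * np.pi * 140 * t)
        y = downsample(x, 1200, 300)
        core = slice(100, -100)
        attenuation_db = 20 * np.log10(np.max(np.abs(y[core])) / 1.0)
        assert attenuation_db <= -40

    def test_non_integer_ratio_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample(rng.standard_normal(1000), 1000, 300)


class TestSegmentDemean:
    def test_min_pretarget_inclusive_at_two_seconds(self, rng):
        s = make_subject(
            rng.standard_normal((3, 2, 1200)), pre_target=[1.9, 2.0, 2.6], fs=300
        )
        out, rep = segment_demean_filter(s)
        assert out.n_trials == 2
        assert rep.counts["T01"]["short_pretarget"] == 1
        assert list(out.trials["pre_target_period"]) == [2.0, 2.6]

    def test_channel_means_are_zero(self, rng):
        s = make_subject(rng.standard_normal((4, 3, 900)) + 5.0)
        out, _ = segment_demean_filter(s)
        np.testing.assert_allclose(
            np.nanmean(out.data, axis=-1), 0.0, atol=1e-5
        )

    def test_constant_signal_becomes_zero(self):
        s = make_subject(np.full((2, 2, 900), 3.7))
        out, _ = segment_demean_filter(s)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-5)


class TestRejectRT:
    def test_strict_bounds(self, rng):
        s = make_subject(rng.standard_normal((3, 2, 900)), rt=[0.25, 0.5, 2.5])
        out, rep = reject_rt(s)
        assert list(out.trials["rt"]) == [0.5]
        assert rep.counts["T01"]["rt_fast"] == 1
        assert rep.counts["T01"]["rt_slow"] == 1

    def test_boundary_values_kept(self, rng):
        s = make_subject(rng.standard_normal((2, 2, 900)), rt=[0.3, 2.0])
        out, _ = reject_rt(s)
        assert out.n_trials == 2


class TestRejectGaze:
    def _subject_with_gaze(self, gaze):
        n_tr, _, n_samp = gaze.shape
        data = np.zeros((n_tr, 2, n_samp), dtype=np.float32)
        return make_subject(data, gaze=gaze, fs=300, pre_target=[2.5] * n_tr)

    def test_long_excursion_rejected_short_kept(self):
        fs, n = 300, int(4.5 * 300)
        t = -1.0 + np.arange(n) / fs
        gaze = np.zeros((2, 2, n), dtype=np.float32)
        gaze[0, 0, (t >= 1.5) & (t < 1.56)] = 2.5  # 0.06 s at 2.5 deg
        gaze[1, 0, (t >= 1.5) & (t < 1.54)] = 3.0  # 0.04 s at 3 deg
        out, rep = reject_gaze(self._subject_with_gaze(gaze))
        assert rep.counts["T01"]["gaze"] == 1
        assert list(out.trials["trial"]) == [1]

    def test_constant_offset_is_drift_corrected(self):
        n = int(4.5 * 300)
        gaze = np.full((1, 2, n), 0.0, dtype=np.float32)
        gaze[0, 0, :] = 2.5  # constant offset incl. the whole pre-cue second
        out, rep = reject_gaze(self._subject_with_gaze(gaze))
        assert out.n_trials == 1 and rep.counts["T01"]["gaze"] == 0

    def test_missing_gaze_distinct_reason(self):
        n = int(4.5 * 300)
        gaze = np.zeros((2, 2, n), dtype=np.float32)
        gaze[0] = np.nan
        out, rep = reject_gaze(self._subject_with_gaze(gaze))
        assert rep.counts["T01"]["gaze_missing"] == 1
        assert out.n_trials == 1


class TestRejectPowerOutliers:
    def test_identical_trials_remove_nothing(self):
        s = make_subject(np.ones((5, 2, 1200)))
        out, rep = reject_power_outliers(s)
        assert out.n_trials == 5 and rep.counts["T01"]["power"] == 0

    def test_single_large_trial_removed(self, rng):
        data = rng.standard_normal((100, 2, 1200)).astype(np.float32)
        data[17] *= 10.0
        s = make_subject(data)
        out, rep = reject_power_outliers(s)
        assert rep.counts["T01"]["power"] == 1
        assert 17 not in out.trials["trial"].to_numpy()

    def test_chance_removal_matches_gaussian_tail(self, rng):
        # per-trial scalars ~ N(mu, 1): removal fraction ~ two-sided 3 SD tail
        scalars = rng.normal(50.0, 1.0, 10_000)
        data = np.sqrt(scalars)[:, None, None] * np.ones((1, 1, 1200), np.float32)
        s = make_subject(data.astype(np.float32))
        _, rep = reject_power_outliers(s)
        frac = rep.counts["T01"]["power"] / 10_000
        expected = 0.0027
        assert abs(frac - expected) <= 3 * np.sqrt(expected / 10_000) + 1e-3

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            reject_power_outliers(make_subject(np.ones((2, 2, 1200))))


class TestCascade:
    def test_exactness_on_injected_artifacts(self, rng):
        cfg = GeneratorConfig.preset("paper", n_subjects=2, n_trials_per_condition=20, seed=9)
        ds = generate_dataset(cfg)
        dirty, injected = inject_artifacts(ds, {"rt": 0.1, "gaze": 0.1, "power": 0.05}, rng)
        clean, report = apply_rejection_cascade(dirty)
        for s in ds.subjects:
            subj = s.subject
            survivors = report.survivors[subj]
            all_injected = np.concatenate(list(injected[subj].values()))
            # no injected trial survives
            assert not np.intersect1d(survivors, all_injected).size
            # RT rule removes exactly the injected extreme-RT trials
            pre = dirty.subjects[[x.subject for x in dirty.subjects].index(subj)]
            long_enough = pre.trials["pre_target_period"].to_numpy() >= 2.0
            expected_rt = np.intersect1d(
                injected[subj]["rt"], np.flatnonzero(long_enough)
            )
            n_rt = report.counts[subj]["rt_fast"] + report.counts[subj]["rt_slow"]
            assert n_rt == len(expected_rt)

    def test_counts_conserve_totals(self, rng):
        cfg = GeneratorConfig.preset("paper", n_subjects=2, n_trials_per_condition=16, seed=2)
        ds = generate_dataset(cfg)
        dirty, _ = inject_artifacts(ds, {"rt": 0.1, "gaze": 0.05}, rng)
        _, report = apply_rejection_cascade(dirty)
        for subj, rules in report.counts.items():
            assert sum(rules.values()) + len(report.survivors[subj]) == report.n_input[subj]

    def test_clean_data_passes_untouched_except_power_chance(self):
        cfg = GeneratorConfig.preset("paper", n_subjects=2, n_trials_per_condition=20, seed=4)
        ds = generate_dataset(cfg)
        _, report = apply_rejection_cascade(ds)
        for subj, rules in report.counts.items():
            assert rules["rt_fast"] == rules["rt_slow"] == 0
            assert rules["gaze"] == rules["gaze_missing"] == 0
            # power rule may remove at most the ~0.27% chance fraction
            assert rules["power"] <= max(2, 0.01 * report.n_input[subj])


class TestPlanarGradient:
    def test_constant_field_maps_to_zero(self, grid30):
        s = make_subject(np.full((2, 30, 600), 4.2))
        planar = to_planar_gradient(s, grid30)
        np.testing.assert_allclose(planar.data_x, 0.0, atol=1e-4)
        np.testing.assert_allclose(planar.data_y, 0.0, atol=1e-4)

    def test_linear_ramp_recovers_gradient(self, grid30):
        field = (2.0 * grid30.positions[:, 0])[None, :, None] * np.ones((1, 1, 600))
        planar = to_planar_gradient(make_subject(field), grid30)
        np.testing.assert_allclose(planar.data_x, 2.0, atol=1e-3)
        np.testing.assert_allclose(planar.data_y, 0.0, atol=1e-3)

    def test_linearity(self, grid30, rng):
        x = rng.standard_normal((2, 30, 300)).astype(np.float32)
        y = rng.standard_normal((2, 30, 300)).astype(np.float32)
        a, b = 1.7, -0.6
        px = to_planar_gradient(make_subject(x), grid30)
        py = to_planar_gradient(make_subject(y), grid30)
        pz = to_planar_gradient(make_subject(a * x + b * y), grid30)
        np.testing.assert_allclose(
            pz.data_x, a * px.data_x + b * py.data_x, atol=1e-3
        )

    def test_single_sensor_bump_localizes_gradient(self, grid30):
        bump = 20  # an interior sensor
        field = np.zeros((1, 30, 100))
        field[:, bump, :] = 1.0
        planar = to_planar_gradient(make_subject(field), grid30)
        mag = np.hypot(planar.data_x, planar.data_y)[0, :, 0]
        near = np.concatenate([[bump], np.flatnonzero(grid30.adjacency[bump])])
        assert np.argmax(mag) in near

    def test_isolated_sensor_rejected(self):
        base = make_sensor_array(10)
        adjacency = base.adjacency.copy()
        adjacency[0, :] = adjacency[:, 0] = False
        lonely = SensorArray(
            labels=base.labels,
            positions=base.positions,
            hemisphere=base.hemisphere,
            adjacency=adjacency,
            posterior=base.posterior,
            neighbor_lists=tuple(
                tuple(np.flatnonzero(adjacency[i])) for i in range(10)
            ),
        )
        with pytest.raises(ValueError, match=str(base.labels[0])):
            to_planar_gradient(make_subject(np.ones((1, 10, 100))), lonely)
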