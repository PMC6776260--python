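"""Wave statistic: plane-wave ground truth, symmetry properties, surrogate
null validity, source mixing and speed conversion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcwaves as pw
from pcwaves import SpaceTimeMap, WaveFixtureSpec, plane_wave_map
from pcwaves.wavemap import MIXING_KERNEL, build_maps, quadrant_stat, source_mixing, surrogate_test, wave_speed

FS = 1000.0


class TestBuildMaps:
    def test_six_second_trial_yields_eleven_windows(self, rng):
        rec = SpaceTimeMap(rng.normal(size=(7, 6000)), FS)
        assert len(build_maps(rec, 1.0, 0.5)) == 11

    def test_window_equal_to_recording_yields_one_map(self, rng):
        rec = SpaceTimeMap(rng.normal(size=(7, 1000)), FS)
        maps = build_maps(rec, 1.0, 0.5)
        assert len(maps) == 1
        np.testing.assert_array_equal(maps[0].data, rec.data)

    def test_minute_long_recording_yields_119_windows(self, rng):
        rec = SpaceTimeMap(rng.normal(size=(7, 60000)), FS)
        assert len(build_maps(rec, 1.0, 0.5)) == 119

    def test_contract_errors(self, rng):
        rec = SpaceTimeMap(rng.normal(size=(7, 800)), FS)
        with pytest.raises(ValueError, match="window exceeds"):
            build_maps(rec, 1.0, 0.5)
        with pytest.raises(ValueError, match="overlap"):
            build_maps(rec, 0.5, 0.5)
        with pytest.raises(ValueError, match="2 channels"):
            SpaceTimeMap(rng.normal(size=(1, 800)), FS)


class TestQuadrantStat:
    def test_forward_plane_wave_positive_ratio_and_peak_location(self):
        m = plane_wave_map(WaveFixtureSpec(temporal_freq_hz=10.0, spatial_freq=1 / 7))
        ws = quadrant_stat(m)
        assert ws.log_ratio > 1.0
        assert ws.peak_temporal_hz == pytest.approx(10.0, abs=1.0)
        assert ws.peak_spatial_cpc == pytest.approx(1 / 7, abs=1e-9)

    def test_backward_plane_wave_mirrors_forward(self):
        fw = quadrant_stat(plane_wave_map(WaveFixtureSpec(spatial_freq=1 / 7)))
        bw = quadrant_stat(plane_wave_map(WaveFixtureSpec(spatial_freq=-1 / 7)))
        # opposite-direction generators are mirrors up to the sampling phase
        assert bw.log_ratio == pytest.approx(-fw.log_ratio, rel=5e-2)
        assert bw.peak_spatial_cpc == pytest.approx(-1 / 7, abs=1e-9)

    def test_standing_wave_scores_exactly_zero(self):
        m = plane_wave_map(WaveFixtureSpec(spatial_freq=0.0))
        assert quadrant_stat(m).log_ratio == 0.0

    def test_constant_map_is_flagged(self):
        ws = quadrant_stat(SpaceTimeMap(np.ones((7, 100)), FS))
        assert ws.constant

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_channel_reversal_antisymmetry_on_arbitrary_maps(self, seed):
        rng = np.random.default_rng(seed)
        m = SpaceTimeMap(rng.normal(size=(7, 200)), FS)
        lr = quadrant_stat(m).log_ratio
        lr_rev = quadrant_stat(m.reversed_channels()).log_ratio
        assert lr_rev == pytest.approx(-lr, abs=1e-10)

    def test_antisymmetry_holds_for_even_channel_counts(self, rng):
        m = SpaceTimeMap(rng.normal(size=(8, 200)), FS)
        assert quadrant_stat(m.reversed_channels()).log_ratio == pytest.approx(
            -quadrant_stat(m).log_ratio, abs=1e-10
        )

    def test_time_reversal_flips_direction_of_a_traveling_wave(self):
        m = plane_wave_map(WaveFixtureSpec(spatial_freq=1 / 7))
        rev = SpaceTimeMap(m.data[:, ::-1].copy(), m.fs)
        assert quadrant_stat(rev).log_ratio == pytest.approx(
            -quadrant_stat(m).log_ratio, rel=5e-2
        )

    def test_noise_dominated_maps_have_no_preferred_direction(self):
        lrs = []
        for seed in range(40):
            m = plane_wave_map(
                WaveFixtureSpec(amplitude=0.05, noise_sd=5.0, spatial_freq=1 / 7, seed=seed)
            )
            lrs.append(quadrant_stat(m).log_ratio)
        assert abs(np.mean(lrs)) < 3 * np.std(lrs) / np.sqrt(len(lrs)) + 0.1


class TestSurrogate:
    def test_shuffled_inputs_produce_no_significant_waves(self, rng):
        """Null validity: feeding channel-shuffled maps leaves both significant
        proportions below 5% and the KS distance near zero."""
        # epoch count of the order the sliding-window analyses produce; the
        # histogram-difference estimator is positively biased for tiny samples
        maps = []
        for seed in range(1200):
            m = plane_wave_map(
                WaveFixtureSpec(duration=0.5, spatial_freq=1 / 7, noise_sd=0.5, seed=seed)
            )
            maps.append(SpaceTimeMap(rng.permutation(m.data, axis=0), FS))
        ens = surrogate_test(maps, n_shuffles=1000, seed=1)
        assert ens.fw_significant_pct < 5.0
        assert ens.bw_significant_pct < 5.0
        assert ens.ks_d < 0.1

    def test_coherent_forward_waves_detected_against_null(self):
        maps = [
            plane_wave_map(WaveFixtureSpec(spatial_freq=1 / 7, noise_sd=0.3, seed=s))
            for s in range(40)
        ]
        ens = surrogate_test(maps, n_shuffles=300, seed=2)
        assert ens.fw_significant_pct > 80.0
        assert ens.bw_significant_pct < 5.0
        assert ens.ks_p < 1e-6

    def test_contracts(self):
        with pytest.raises(ValueError, match="at least one map"):
            surrogate_test([], n_shuffles=500)
        m = plane_wave_map(WaveFixtureSpec())
        with pytest.raises(ValueError, match="n_shuffles"):
            surrogate_test([m], n_shuffles=10)

    def test_null_size_and_determinism(self):
        maps = [
            plane_wave_map(WaveFixtureSpec(duration=0.5, spatial_freq=1 / 7, noise_sd=0.3, seed=s))
            for s in range(5)
        ]
        a = surrogate_test(maps, n_shuffles=200, seed=3)
        b = surrogate_test(maps, n_shuffles=200, seed=3)
        assert a.null.size == 200 * len(maps)
        np.testing.assert_array_equal(a.null, b.null)
        assert a.fw_significant_pct == b.fw_significant_pct


class TestSourceMixing:
    def test_identity_kernel_is_identity(self, rng):
        m = SpaceTimeMap(rng.normal(size=(7, 300)), FS)
        out = source_mixing(m, np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(out.data, m.data, atol=1e-12)

    def test_direction_preserved_under_default_kernel(self):
        m = plane_wave_map(WaveFixtureSpec(spatial_freq=1 / 7, noise_sd=0.1, seed=0))
        assert np.sign(quadrant_stat(source_mixing(m)).log_ratio) == np.sign(
            quadrant_stat(m).log_ratio
        )

    def test_mixing_flattens_phase_gradient_and_raises_apparent_speed(self):
        steep = plane_wave_map(WaveFixtureSpec(spatial_freq=3 / 7))
        before = wave_speed(steep, 0.02)
        after = wave_speed(source_mixing(steep), 0.02)
        assert after > before

    def test_kernel_contracts(self, rng):
        m = SpaceTimeMap(rng.normal(size=(7, 100)), FS)
        with pytest.raises(ValueError, match="odd"):
            source_mixing(m, np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="wider"):
            source_mixing(m, np.ones(15))
        assert MIXING_KERNEL.size == 7  # 1 at center, 0.8/0.6/0.4 by distance


class TestWaveSpeed:
    def test_plane_wave_speed_from_definition(self):
        m = plane_wave_map(WaveFixtureSpec(temporal_freq_hz=10.0, spatial_freq=1 / 7))
        assert wave_speed(m, 0.02) == pytest.approx(10.0 / (1 / 7) * 0.02, rel=1e-6)

    def test_standing_wave_speed_is_undefined_marker(self):
        m = plane_wave_map(WaveFixtureSpec(spatial_freq=0.0))
        assert np.isinf(wave_speed(m, 0.02))

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            wave_speed(SpaceTimeMap(np.zeros((7, 100)), FS), 0.02)


def test_multilevel_model_wave_frequency_in_alpha_band(multilevel_input_run):
    run, _ = multilevel_input_run
    maps = pw.maps_from_trials(run.predictions)
    freqs = [quadrant_stat(m).peak_temporal_hz for m in maps]
    assert 8.0 <= np.median(freqs) <= 13.0
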