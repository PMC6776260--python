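"""Cross-correlation IRF estimator: known systems, dual implementation, spectra."""

from __future__ import annotations

import numpy as np
import pytest

from pcwaves import IRF, TimeSeriesSet, crosscorrelate, crosscorrelate_trials, irf_spectrum
from pcwaves.synth import NoiseSpec, white_noise

FS = 1000.0


def test_identity_system_gives_autocorrelation_peak_at_zero_lag(rng):
    drive = white_noise(NoiseSpec(duration=2.0, cutoff_hz=500.0), 5, rng=rng)
    irf = crosscorrelate(drive, drive, max_lag_ms=200.0)
    assert int(np.argmax(irf.values)) == 0
    assert irf.values[0] == pytest.approx(1.0, rel=1e-6)  # correlation of x with x
    assert np.all(np.abs(irf.values[10:]) < 0.2)


def test_pure_delay_system_peaks_at_the_delay(rng):
    drive = white_noise(NoiseSpec(duration=2.0, cutoff_hz=500.0), 3, rng=rng)
    delayed = np.roll(drive.data, 50, axis=1)
    delayed[:, :50] = 0.0
    irf = crosscorrelate(TimeSeriesSet(delayed, FS), drive, max_lag_ms=200.0)
    assert int(np.argmax(irf.values)) == 50


def _direct_xcorr(sig: np.ndarray, drv: np.ndarray, n_lags: int) -> np.ndarray:
    """Sliding-dot-product oracle, coefficient-normalised like the package."""
    s = sig - sig.mean()
    g = drv - drv.mean()
    out = np.empty(n_lags)
    for k in range(n_lags):
        out[k] = np.dot(g[: g.size - k], s[k:]) / (g.size - k)
    return out / (g.std() * s.std())


def test_fft_implementation_matches_direct_sliding_dot_product(rng):
    sig = rng.normal(size=1000)
    drv = rng.normal(size=1000)
    fft_based = crosscorrelate_trials(
        TimeSeriesSet(sig, FS), TimeSeriesSet(drv, FS), max_lag_ms=300.0
    )[0]
    direct = _direct_xcorr(sig, drv, 301)
    np.testing.assert_allclose(fft_based, direct, atol=1e-10)


def test_spectrum_of_pure_cosine_peaks_at_its_frequency():
    t = np.arange(1000) / FS
    irf = IRF(t * 1000.0, np.cos(2 * np.pi * 10.0 * t), FS)
    summary = irf_spectrum(irf)
    assert summary.peak_frequency_hz == pytest.approx(10.0, abs=1.0)
    assert summary.oscillatory


def test_all_zero_irf_flagged_not_oscillatory():
    irf = IRF(np.arange(100.0), np.zeros(100), FS)
    summary = irf_spectrum(irf)
    assert summary.peak_amplitude == 0.0
    assert not summary.oscillatory


def test_shape_and_lag_contracts(rng):
    a = TimeSeriesSet(rng.normal(size=(2, 500)), FS)
    b = TimeSeriesSet(rng.normal(size=(3, 500)), FS)
    with pytest.raises(ValueError, match="shapes differ"):
        crosscorrelate(a, b)
    with pytest.raises(ValueError, match="exceeds trial length"):
        crosscorrelate(a, TimeSeriesSet(rng.normal(size=(2, 500)), FS), max_lag_ms=600.0)


def test_two_area_model_irf_oscillates_at_alpha(two_area_run):
    """Delay 12 ms, tau 17 ms: the trial-averaged echo rings at ~10 Hz for
    several cycles, matching the characteristic-equation prediction."""
    run, drives = two_area_run
    irf = crosscorrelate(run.predictions[-1], drives.input)
    spec = irf_spectrum(irf)
    assert 9.0 <= spec.peak_frequency_hz <= 11.5
    # several cycles visible: oscillation energy well above the 700-1000 ms tail
    v = irf.values
    assert np.std(v[:400]) > 3 * np.std(v[800:])


def test_more_trials_reduce_irf_variance(rng):
    """For two independent noise streams the true IRF is zero everywhere, so
    the trial-averaged estimate must shrink as trials accumulate."""
    sig = white_noise(NoiseSpec(duration=2.0, cutoff_hz=500.0), 40, rng=rng)
    drv = white_noise(NoiseSpec(duration=2.0, cutoff_hz=500.0), 40, rng=rng)
    per_trial = crosscorrelate_trials(sig, drv, 500.0)
    few = per_trial[:4].mean(axis=0)
    many = per_trial.mean(axis=0)
    assert np.std(many) < 0.6 * np.std(few)
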