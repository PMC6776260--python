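"""Impulse-response estimation by cross-correlation with the drive sequence.

Cross-correlating a white-noise drive with a (simulated or recorded) response
recovers the system's impulse response function (IRF) — the "perceptual echo"
of the stimulation literature. The default estimator is the lag-wise Pearson
correlation between the mean-centered drive and response, averaged over
trials; covariance normalisations are available as options. Lags reaching
past the trial end are averaged over the valid overlap only (unbiased
estimator), not zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .signals import TimeSeriesSet

__all__ = ["IRF", "SpectrumSummary", "crosscorrelate", "crosscorrelate_trials", "irf_spectrum"]


@dataclass
class IRF:
    """Trial-averaged impulse response: one value per non-negative lag."""

    lags_ms: np.ndarray
    values: np.ndarray
    fs: float
    source: str = ""
    drive: str = ""

    @property
    def n_lags(self) -> int:
        return self.values.size


@dataclass
class SpectrumSummary:
    """Amplitude spectrum of an IRF with its dominant peak."""

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray
    peak_frequency_hz: float
    peak_amplitude: float
    oscillatory: bool = True


def _xcorr_core(
    sig: np.ndarray, drv: np.ndarray, n_lags: int, normalization: str = "coeff"
) -> np.ndarray:
    """Per-trial cross-correlation of drive (leading) with signal, lags 0..n_lags-1.

    Both inputs (trials, time) are mean-centered per trial and the lag-wise
    sum is divided by the valid overlap length (unbiased estimator). The
    result is then scaled according to ``normalization``:

    * ``"coeff"`` (default) — correlation coefficient per lag (divide by the
      product of the drive and signal standard deviations); lags where the
      two series are proportional score 1. This is the conventional IRF /
      perceptual-echo estimator and puts channels of very different response
      amplitude on a common scale.
    * ``"unit-drive"`` — covariance divided by the drive variance: response
      per unit drive, invariant under drive rescaling.
    * ``"cov"`` — raw lag-wise covariance.
    """
    sig = sig - sig.mean(axis=1, keepdims=True)
    drv = drv - drv.mean(axis=1, keepdims=True)
    n_t = sig.shape[1]
    nfft = sp_fft.next_fast_len(n_t + n_lags)
    s = sp_fft.rfft(sig, nfft, axis=1)
    g = sp_fft.rfft(drv, nfft, axis=1)
    # irfft(S * conj(G))[k] = sum_t drv[t] * sig[t + k] (linear, zero-padded)
    r = sp_fft.irfft(s * np.conj(g), nfft, axis=1)[:, :n_lags]
    counts = n_t - np.arange(n_lags)
    cov = r / counts
    if normalization == "cov":
        return cov
    # constant traces have zero variance; their correlation is defined as 0
    sd_g = drv.std(axis=1, keepdims=True)
    sd_g[sd_g == 0] = np.inf
    if normalization == "unit-drive":
        return cov / sd_g**2
    if normalization == "coeff":
        sd_s = sig.std(axis=1, keepdims=True)
        sd_s[sd_s == 0] = np.inf
        return cov / (sd_g * sd_s)
    raise ValueError(f"unknown normalization {normalization!r}")


def crosscorrelate_trials(
    signal: TimeSeriesSet,
    drive: TimeSeriesSet,
    max_lag_ms: float = 1000.0,
    normalization: str = "coeff",
) -> np.ndarray:
    """Per-trial IRFs, shape (trials, n_lags), without averaging."""
    if signal.data.shape != drive.data.shape:
        raise ValueError(
            f"signal {signal.data.shape} and drive {drive.data.shape} shapes differ"
        )
    if abs(signal.fs - drive.fs) > 1e-9:
        raise ValueError("signal and drive sampling rates differ")
    n_lags = int(round(max_lag_ms * signal.fs / 1000.0)) + 1
    if n_lags > signal.n_samples:
        raise ValueError(
            f"max_lag {max_lag_ms} ms exceeds trial length "
            f"{1000.0 * signal.n_samples / signal.fs} ms"
        )
    return _xcorr_core(signal.data, drive.data, n_lags, normalization)


def crosscorrelate(
    signal: TimeSeriesSet,
    drive: TimeSeriesSet,
    max_lag_ms: float = 1000.0,
    normalization: str = "coeff",
    source: str = "",
    drive_name: str = "",
) -> IRF:
    """Trial-averaged IRF of ``signal`` with respect to ``drive`` (drive leads)."""
    per_trial = crosscorrelate_trials(signal, drive, max_lag_ms, normalization)
    values = per_trial.mean(axis=0)
    lags = np.arange(values.size) * 1000.0 / signal.fs
    return IRF(lags, values, signal.fs, source=source, drive=drive_name)


def irf_spectrum(irf: IRF, floor_hz: float = 2.0) -> SpectrumSummary:
    """Amplitude spectrum of the mean-removed IRF and its spectral peak.

    The peak is the amplitude maximum at or above ``floor_hz`` (default 2 Hz,
    skipping DC leakage). An all-zero IRF returns a zero-amplitude summary
    flagged non-oscillatory.
    """
    v = irf.values - irf.values.mean()
    n = v.size
    if n == 0:
        raise ValueError("empty IRF")
    amps = np.abs(sp_fft.rfft(v)) / n
    freqs = sp_fft.rfftfreq(n, d=1.0 / irf.fs)
    if not np.any(np.abs(v) > 0):
        return SpectrumSummary(freqs, amps, 0.0, 0.0, oscillatory=False)
    sel = freqs >= floor_hz
    if not sel.any():
        raise ValueError("floor frequency excludes the whole spectrum")
    i = int(np.argmax(amps[sel]))
    peak_f = float(freqs[sel][i])
    peak_a = float(amps[sel][i])
    return SpectrumSummary(freqs, amps, peak_f, peak_a, oscillatory=peak_a > 0)
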