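"""Synthetic signal generators: band-limited white noise and plane-wave maps.

The white-noise generator emulates the random luminance sequences used to
drive the model: zero-mean sequences with a flat power spectrum up to a cutoff
(80 Hz by default, matching a stimulus refreshed at 160 Hz). Band-limiting is
done in the frequency domain — unit-magnitude coefficients with uniform random
phases below the cutoff, zero above — so the "flat to cutoff" property holds
exactly by construction.

The plane-wave generator produces channels x time maps with a known traveling
direction and speed, the ground-truth fixtures against which the wave
statistic is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import SpaceTimeMap, TimeSeriesSet

__all__ = ["NoiseSpec", "WaveFixtureSpec", "white_noise", "plane_wave_map"]


@dataclass
class NoiseSpec:
    """Specification of a band-limited flat-spectrum noise sequence.

    duration : seconds per trial.
    fs : sampling rate, Hz.
    cutoff_hz : spectrum is flat below this frequency and zero above; must not
        exceed the Nyquist frequency.
    variance : target sample variance (enforced exactly per trial).
    seed : RNG seed; generation is deterministic given the seed.
    """

    duration: float = 3.0
    fs: float = 1000.0
    cutoff_hz: float = 80.0
    variance: float = 1.0
    seed: int | None = None


@dataclass
class WaveFixtureSpec:
    """Specification of a noisy plane-wave space-time map.

    spatial_freq is in cycles/channel and signed: positive values travel from
    low to high channel index (forward), negative the reverse, zero yields a
    standing wave (all channels in phase).
    """

    n_channels: int = 7
    duration: float = 1.0
    fs: float = 1000.0
    temporal_freq_hz: float = 10.0
    spatial_freq: float = 1.0 / 7.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    phase: float = 0.0
    seed: int | None = None


def white_noise(spec: NoiseSpec, n_trials: int = 1, rng: np.random.Generator | None = None) -> TimeSeriesSet:
    """Generate independent band-limited white-noise trials.

    Each trial is built from unit-magnitude Fourier coefficients with i.i.d.
    uniform phases for 0 < f <= cutoff and zero elsewhere (DC included, so the
    mean is exactly zero), then rescaled to the target variance.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    if n < 2:
        raise ValueError("duration too short for the given sampling rate")
    nyquist = spec.fs / 2.0
    if spec.cutoff_hz > nyquist + 1e-12:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz exceeds Nyquist {nyquist} Hz")

    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    band = (freqs > 0) & (freqs <= spec.cutoff_hz + 1e-12)
    spectrum = np.zeros((n_trials, freqs.size), dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, int(band.sum())))
    spectrum[:, band] = np.exp(1j * phases)
    # Nyquist coefficient of a real signal must be real.
    if n % 2 == 0 and band[-1]:
        spectrum[:, -1] = np.sign(np.cos(phases[:, -1]))
    x = np.fft.irfft(spectrum, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    x = x / sd * np.sqrt(spec.variance)
    return TimeSeriesSet(x, spec.fs)


def plane_wave_map(spec: WaveFixtureSpec, rng: np.random.Generator | None = None) -> SpaceTimeMap:
    """Generate ``cos(2π f t − 2π k·channel + φ)`` plus optional white noise."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    c = np.arange(spec.n_channels)
    phase = 2.0 * np.pi * (spec.temporal_freq_hz * t[None, :] - spec.spatial_freq * c[:, None])
    data = spec.amplitude * np.cos(phase + spec.phase)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    meta = {
        "temporal_freq_hz": spec.temporal_freq_hz,
        "spatial_freq": spec.spatial_freq,
        "amplitude": spec.amplitude,
        "noise_sd": spec.noise_sd,
    }
    return SpaceTimeMap(data, spec.fs, meta=meta)
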