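"""Traveling-wave quantification via the 2D Fourier quadrant log ratio.

A channels x time map of an oscillation that travels across ordered channels
concentrates its 2D Fourier energy off the zero-spatial-frequency axis: the
sign pairing of spatial and temporal frequency encodes the direction of
travel. With rows ordered low-to-high (hierarchy level, or posterior-to-
anterior electrode), a forward wave ``cos(2π f t − 2π κ c)`` with κ > 0 peaks
at (positive temporal frequency, negative spatial DFT frequency) and its
mirror quadrant holds backward waves.

The statistic extracts the maximum 2D-spectrum magnitude in each quadrant
(the zero-spatial-frequency midline row is included in both, so a standing
wave scores identically in the two quadrants) and reports

    log_ratio = log( max_FW / max_BW )

— positive for forward waves, negative for backward, zero for standing waves
or direction balance. Statistical reliability is assessed against a surrogate
null built by shuffling the channel order, which destroys the spatial
ordering while preserving every per-channel spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import stats

from .signals import SpaceTimeMap, TimeSeriesSet
from .irf import crosscorrelate_trials

__all__ = [
    "WaveStat",
    "SurrogateEnsemble",
    "build_maps",
    "maps_from_trials",
    "irf_maps",
    "quadrant_stat",
    "surrogate_test",
    "source_mixing",
    "wave_speed",
    "MIXING_KERNEL",
]

# Distance-weighted source-mixing kernel: contribution 1 at the matching
# level, decaying to 0.8, 0.6, 0.4 at hierarchical distances 1, 2, 3 and zero
# beyond (scalp electrodes see a blurred average of nearby cortical sources).
MIXING_KERNEL = np.array([0.4, 0.6, 0.8, 1.0, 0.8, 0.6, 0.4])


@dataclass
class WaveStat:
    """Quadrant maxima and log ratio for one space-time map.

    ``peak_temporal_hz`` / ``peak_spatial_cpc`` locate the overall spectral
    maximum (over both quadrants); spatial frequency is signed, positive for
    forward travel. ``constant`` flags a (numerically) constant input map.
    """

    fw_power: float
    bw_power: float
    log_ratio: float
    peak_temporal_hz: float
    peak_spatial_cpc: float
    constant: bool = False


@dataclass
class SurrogateEnsemble:
    """Real log-ratio sample, channel-shuffle null, and derived summaries.

    ``fw_significant_pct`` / ``bw_significant_pct`` are the percentages of
    wave events beyond chance: the positive part of the (real - null)
    histogram-density difference summed over positive / negative log-ratio
    bins. ``ks_d`` / ``ks_p`` give the two-sample Kolmogorov-Smirnov
    comparison of the real and pooled-null samples.
    """

    real: np.ndarray
    null: np.ndarray
    n_shuffles: int
    fw_significant_pct: float
    bw_significant_pct: float
    ks_d: float
    ks_p: float
    bin_edges: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def build_maps(
    recording: SpaceTimeMap, window_s: float = 1.0, overlap_s: float = 0.5
) -> list[SpaceTimeMap]:
    """Tile a recording into sliding-window maps (1 s / 500 ms overlap default).

    A 6-s recording yields 11 windows; a window equal to the recording length
    yields exactly one map.
    """
    n_win = int(round(window_s * recording.fs))
    stride = n_win - int(round(overlap_s * recording.fs))
    if stride <= 0:
        raise ValueError("overlap must be smaller than the window")
    if n_win > recording.n_samples:
        raise ValueError("window exceeds recording length")
    maps = []
    for i, start in enumerate(range(0, recording.n_samples - n_win + 1, stride)):
        maps.append(
            SpaceTimeMap(
                recording.data[:, start : start + n_win],
                recording.fs,
                recording.channel_names,
                window_id=i,
                meta=dict(recording.meta),
            )
        )
    return maps


def maps_from_trials(
    levels: list[TimeSeriesSet], window_s: float = 1.0, overlap_s: float = 0.5
) -> list[SpaceTimeMap]:
    """Sliding-window maps from per-level trial sets (one recording per trial)."""
    stack = np.stack([ts.data for ts in levels], axis=1)  # (trials, levels, time)
    fs = levels[0].fs
    out: list[SpaceTimeMap] = []
    for tr in range(stack.shape[0]):
        rec = SpaceTimeMap(stack[tr], fs, meta={"trial": tr})
        out.extend(build_maps(rec, window_s, overlap_s))
    return out


def irf_maps(
    levels: list[TimeSeriesSet],
    drive: TimeSeriesSet,
    max_lag_ms: float = 1000.0,
    average: bool = False,
    normalization: str = "coeff",
) -> list[SpaceTimeMap]:
    """Per-trial (or trial-averaged) levels x lag IRF maps.

    Each level's trace is cross-correlated with the drive; stacking the IRFs
    of all levels gives a map whose "time" axis is the correlation lag (the
    IRF support, 1 s by default).
    """
    per_level = [crosscorrelate_trials(ts, drive, max_lag_ms, normalization) for ts in levels]
    cube = np.stack(per_level, axis=1)  # (trials, levels, lags)
    fs = levels[0].fs
    if average:
        return [SpaceTimeMap(cube.mean(axis=0), fs, meta={"trial": "mean"})]
    return [SpaceTimeMap(cube[tr], fs, meta={"trial": tr}) for tr in range(cube.shape[0])]


def _row_spectrum(data: np.ndarray) -> np.ndarray:
    """Temporal rFFT of each mean-centered row; DC column dropped."""
    centered = data - data.mean(axis=1, keepdims=True)
    return sp_fft.rfft(centered, axis=1)[:, 1:]


def _quadrant_maxima(chan_fft_mag: np.ndarray) -> tuple[float, float, tuple[int, int], tuple[int, int]]:
    """FW/BW maxima of a (channels, positive temporal freq) magnitude array.

    Rows are spatial DFT indices (np.fft.fft along channels). Negative spatial
    frequencies pair with positive temporal frequencies for forward travel;
    the zero-spatial-frequency row 0 is included in both quadrants.
    """
    c = chan_fft_mag.shape[0]
    neg, pos = _fw_bw_rows(c)
    fw_rows = np.concatenate(([0], neg))
    bw_rows = np.concatenate(([0], pos))
    fw_block = chan_fft_mag[fw_rows]
    bw_block = chan_fft_mag[bw_rows]
    fi = np.unravel_index(int(np.argmax(fw_block)), fw_block.shape)
    bi = np.unravel_index(int(np.argmax(bw_block)), bw_block.shape)
    fw_peak = (int(fw_rows[fi[0]]), int(fi[1]))
    bw_peak = (int(bw_rows[bi[0]]), int(bi[1]))
    return float(fw_block[fi]), float(bw_block[bi]), fw_peak, bw_peak


def quadrant_stat(m: SpaceTimeMap) -> WaveStat:
    """2D-FFT quadrant maxima and log ratio of one map.

    Rows are mean-centered, the 2D spectrum is taken (temporal rFFT then
    channel FFT), the temporal DC column is excluded, and the maximum
    magnitude is read off each direction quadrant (midline row in both).
    """
    if not np.all(np.isfinite(m.data)):
        raise ValueError("map contains non-finite values")
    row_fft = _row_spectrum(m.data)
    mag = np.abs(sp_fft.fft(row_fft, axis=0))
    if not np.any(mag > 0):
        return WaveStat(0.0, 0.0, 0.0, 0.0, 0.0, constant=True)
    fw, bw, fw_peak, bw_peak = _quadrant_maxima(mag)
    log_ratio = float(np.log(fw / bw))
    peak = fw_peak if fw >= bw else bw_peak
    spatial = np.fft.fftfreq(m.n_channels)[peak[0]]
    # sign convention: forward (low -> high channel) positive
    signed_spatial = -spatial
    temporal_hz = (peak[1] + 1) * m.fs / m.n_samples  # +1: DC column was dropped
    return WaveStat(fw, bw, log_ratio, float(temporal_hz), float(signed_spatial))


def _null_log_ratios(
    m: SpaceTimeMap, n_shuffles: int, rng: np.random.Generator, chunk: int = 250
) -> np.ndarray:
    """Log ratios of ``n_shuffles`` fresh channel permutations of one map.

    Row permutation commutes with the temporal FFT, so the per-row spectrum is
    computed once and only the channel-axis FFT is redone per permutation.
    The identity permutation is excluded from the null.
    """
    c = m.n_channels
    row_fft = _row_spectrum(m.data)
    idx = np.arange(c)
    out = np.empty(n_shuffles)
    done = 0
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        perms = rng.permuted(np.tile(idx, (k, 1)), axis=1)
        bad = (perms == idx).all(axis=1)
        while bad.any():
            perms[bad] = rng.permuted(np.tile(idx, (int(bad.sum()), 1)), axis=1)
            bad = (perms == idx).all(axis=1)
        mag = np.abs(sp_fft.fft(row_fft[perms], axis=1))  # (k, c, f)
        neg0, pos0 = _fw_bw_rows(c)
        fw = mag[:, np.concatenate(([0], neg0)), :].max(axis=(1, 2))
        bw = mag[:, np.concatenate(([0], pos0)), :].max(axis=(1, 2))
        out[done : done + k] = np.log(fw / bw)
        done += k
    return out


def _fw_bw_rows(c: int) -> tuple[np.ndarray, np.ndarray]:
    """Spatial DFT row indices with negative / positive frequency.

    For an even channel count the spatial Nyquist row is its own mirror and is
    excluded from both quadrants so the statistic stays exactly antisymmetric
    under channel reversal.
    """
    freqs = np.fft.fftfreq(c)
    neg = np.where(freqs < 0)[0]
    if c % 2 == 0:
        neg = neg[neg != c // 2]
    return neg, np.where(freqs > 0)[0]


def surrogate_test(
    maps: list[SpaceTimeMap],
    n_shuffles: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_bins: int = 50,
) -> SurrogateEnsemble:
    """Channel-order shuffle test of wave reliability over a set of maps.

    For each map the real log ratio is computed, plus ``n_shuffles`` null log
    ratios from fresh random channel permutations; nulls are pooled across
    maps. Real and null samples are histogrammed on shared equal-width bins
    and the significant-wave proportions are the positive part of the density
    difference summed over positive (FW) and negative (BW) bins. A two-sample
    KS statistic between the real and pooled null samples is also reported.
    """
    if not maps:
        raise ValueError("need at least one map")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a usable null")
    if rng is None:
        rng = np.random.default_rng(seed)
    real = np.array([quadrant_stat(m).log_ratio for m in maps])
    null = np.concatenate([_null_log_ratios(m, n_shuffles, rng) for m in maps])

    lo = min(real.min(), null.min())
    hi = max(real.max(), null.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    real_mass, _ = np.histogram(real, bins=edges)
    null_mass, _ = np.histogram(null, bins=edges)
    diff = real_mass / real.size - null_mass / null.size
    centers = 0.5 * (edges[:-1] + edges[1:])
    fw_pct = 100.0 * float(np.clip(diff[centers > 0], 0, None).sum())
    bw_pct = 100.0 * float(np.clip(diff[centers < 0], 0, None).sum())
    ks = stats.ks_2samp(real, null)
    return SurrogateEnsemble(
        real=real,
        null=null,
        n_shuffles=n_shuffles,
        fw_significant_pct=fw_pct,
        bw_significant_pct=bw_pct,
        ks_d=float(ks.statistic),
        ks_p=float(ks.pvalue),
        bin_edges=edges,
    )


def source_mixing(m: SpaceTimeMap, weights: np.ndarray | None = None) -> SpaceTimeMap:
    """Distance-weighted average across channels (scalp source mixing).

    Each output channel is the weighted mean of input channels by hierarchical
    distance, with the kernel truncated and renormalised at the edges. The
    identity kernel returns the map unchanged.
    """
    w = MIXING_KERNEL if weights is None else np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    c = m.n_channels
    if w.size > 2 * c - 1:
        raise ValueError("kernel wider than 2*channels - 1")
    half = w.size // 2
    out = np.empty_like(m.data)
    for i in range(c):
        lo = max(0, i - half)
        hi = min(c, i + half + 1)
        ww = w[lo - i + half : hi - i + half]
        out[i] = ww @ m.data[lo:hi] / ww.sum()
    meta = dict(m.meta)
    meta["source_mixed"] = True
    return SpaceTimeMap(out, m.fs, m.channel_names, m.window_id, meta)


def wave_speed(m: SpaceTimeMap, inter_channel_distance_m: float = 0.02) -> float:
    """Propagation speed implied by the dominant off-axis 2D-spectral peak.

    speed = (peak temporal frequency [Hz] / |peak spatial frequency|
    [cycles/channel]) x inter-channel distance [m]. Standing-wave maps (the
    off-axis spectrum carries no energy) return ``inf``.
    """
    row_fft = _row_spectrum(m.data)
    mag = np.abs(sp_fft.fft(row_fft, axis=0))
    if not np.any(mag > 0):
        raise ValueError("constant map has no defined speed")
    off_rows = np.concatenate(_fw_bw_rows(m.n_channels))
    block = mag[off_rows]
    ri, ci = np.unravel_index(int(np.argmax(block)), block.shape)
    spatial = abs(np.fft.fftfreq(m.n_channels)[off_rows[ri]])
    # Standing wave: the midline row dominates even the best off-axis bin.
    if mag[0].max() > 0 and block[ri, ci] < 1e-9 * mag[0].max():
        return float("inf")
    temporal_hz = (ci + 1) * m.fs / m.n_samples
    return float(temporal_hz / spatial * inter_channel_distance_m)
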