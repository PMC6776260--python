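"""Parameter-space exploration and per-level timescale characterization.

Three grid scans reproduce the model's regime maps:

* :func:`scan_two_level` — IRF spectral peak (frequency, amplitude) over a
  (τ, ΔT) grid for the two-area model; alpha-band peaks fill the
  physiological range 10 <= ΔT <= 15 ms, 15 <= τ <= 25 ms.
* :func:`scan_multilevel` — mean wave log ratio and peak temporal frequency
  over (τ, ΔT) for the 7-level model, input- or prior-driven.
* :func:`scan_tau_d` — behaviour as the decay constant τ_D approaches τ:
  log ratios collapse to zero (waves vanish) and the peak frequency drifts
  up toward ~15 Hz.

:func:`characterize_timescales` fits a decaying exponential to each level's
prediction autocorrelation; the fitted constants θ_L grow with hierarchical
level into the 100-500 ms range even though every level shares the same
integration constant τ — the network, not the neuron, sets the timescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from .irf import crosscorrelate, irf_spectrum
from .model import ModelConfig, SimulationRun, simulate_trials
from .wavemap import maps_from_trials, quadrant_stat

__all__ = [
    "GridResult",
    "scan_two_level",
    "scan_multilevel",
    "scan_tau_d",
    "characterize_timescales",
]


@dataclass
class GridResult:
    """Tidy table of per-cell scan results plus the scan settings."""

    table: pd.DataFrame
    axes: dict
    n_trials: int
    seed: int | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def scan_two_level(
    tau_grid,
    deltat_grid,
    n_trials: int = 200,
    duration: float = 3.0,
    seed: int | None = None,
    base: ModelConfig | None = None,
) -> GridResult:
    """IRF peak frequency/amplitude of the two-area model over a (τ, ΔT) grid.

    Each cell runs ``n_trials`` white-noise trials, cross-correlates the
    prediction with the input and reads the spectral peak of the averaged IRF.
    Diverging cells are flagged (``diverged`` column), not fatal.
    """
    base = base or ModelConfig(n_levels=1)
    rng = np.random.default_rng(seed)
    rows = []
    for tau in tau_grid:
        for dt_ in deltat_grid:
            cfg = ModelConfig(
                n_levels=base.n_levels, delta_t=float(dt_), tau=float(tau), tau_d=base.tau_d
            )
            rec = {"tau": tau, "delta_t": dt_, "diverged": False}
            try:
                run, drives = simulate_trials(cfg, duration, n_trials, "input", rng=rng)
                irf = crosscorrelate(run.predictions[-1], drives.input)
                spec = irf_spectrum(irf)
                rec["peak_freq_hz"] = spec.peak_frequency_hz
                rec["peak_amplitude"] = spec.peak_amplitude
            except Exception:
                rec.update(peak_freq_hz=np.nan, peak_amplitude=np.nan, diverged=True)
            rows.append(rec)
    return GridResult(
        pd.DataFrame(rows),
        {"tau": list(tau_grid), "delta_t": list(deltat_grid)},
        n_trials,
        seed,
    )


def scan_multilevel(
    tau_grid,
    deltat_grid,
    drive_mode: str = "input",
    n_trials: int = 20,
    duration: float = 6.0,
    n_levels: int = 7,
    seed: int | None = None,
) -> GridResult:
    """Wave log ratio and 2D-spectral peak frequency over (τ, ΔT), multilevel.

    Per cell: mean log ratio over all sliding-window maps (positive = forward),
    the median peak temporal frequency, and the mean peak spectral power.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tau in tau_grid:
        for dt_ in deltat_grid:
            cfg = ModelConfig(n_levels=n_levels, delta_t=float(dt_), tau=float(tau))
            rec = {"tau": tau, "delta_t": dt_, "diverged": False}
            try:
                run, _ = simulate_trials(cfg, duration, n_trials, drive_mode, rng=rng)
                stats = [quadrant_stat(m) for m in maps_from_trials(run.predictions)]
                rec["mean_log_ratio"] = float(np.mean([s.log_ratio for s in stats]))
                rec["peak_freq_hz"] = float(np.median([s.peak_temporal_hz for s in stats]))
                rec["peak_power"] = float(np.mean([max(s.fw_power, s.bw_power) for s in stats]))
            except Exception:
                rec.update(mean_log_ratio=np.nan, peak_freq_hz=np.nan, peak_power=np.nan, diverged=True)
            rows.append(rec)
    return GridResult(
        pd.DataFrame(rows),
        {"tau": list(tau_grid), "delta_t": list(deltat_grid), "drive_mode": drive_mode},
        n_trials,
        seed,
    )


def scan_tau_d(
    tau_d_values=None,
    tau: float = 20.0,
    delta_t: float = 12.0,
    n_replicates: int = 20,
    duration: float = 6.0,
    drive_mode: str = "input",
    n_levels: int = 7,
    seed: int | None = None,
) -> GridResult:
    """Sweep the decay constant τ_D at fixed (τ, ΔT), 20 replicates per value.

    Default sweep 20..200 ms in steps of 5. Replicates are independent trials;
    each contributes its sliding-window mean log ratio, peak power and peak
    frequency, then replicates are averaged per τ_D value.
    """
    if tau_d_values is None:
        tau_d_values = np.arange(20, 201, 5)
    rng = np.random.default_rng(seed)
    rows = []
    for td in tau_d_values:
        cfg = ModelConfig(n_levels=n_levels, delta_t=delta_t, tau=tau, tau_d=float(td))
        run, _ = simulate_trials(cfg, duration, n_replicates, drive_mode, rng=rng)
        lrs, pows, freqs = [], [], []
        for tr in range(n_replicates):
            one = [
                quadrant_stat(m)
                for m in maps_from_trials(
                    [type(p)(p.data[tr : tr + 1], p.fs) for p in run.predictions]
                )
            ]
            lrs.append(np.mean([s.log_ratio for s in one]))
            pows.append(np.mean([max(s.fw_power, s.bw_power) for s in one]))
            freqs.append(np.median([s.peak_temporal_hz for s in one]))
        rows.append(
            {
                "tau_d": td,
                "mean_log_ratio": float(np.mean(lrs)),
                "sd_log_ratio": float(np.std(lrs)),
                "mean_peak_power": float(np.mean(pows)),
                "mean_peak_freq_hz": float(np.mean(freqs)),
            }
        )
    return GridResult(
        pd.DataFrame(rows),
        {"tau_d": list(np.asarray(tau_d_values).tolist()), "tau": tau, "delta_t": delta_t},
        n_replicates,
        seed,
    )


def autocorrelation(data: np.ndarray, n_lag: int) -> np.ndarray:
    """Trial-averaged normalised autocorrelation at lags 0..n_lag.

    Each trial is mean-centered, its autocorrelation computed by FFT, and the
    per-trial functions (normalised to 1 at lag 0) are averaged.
    """
    x = data - data.mean(axis=1, keepdims=True)
    n_t = x.shape[1]
    nfft = sp_fft.next_fast_len(2 * n_t)
    ps = np.abs(sp_fft.rfft(x, nfft, axis=1)) ** 2
    ac = sp_fft.irfft(ps, nfft, axis=1)[:, : n_lag + 1]
    return (ac / ac[:, :1]).mean(axis=0)


def characterize_timescales(
    run: SimulationRun,
    max_lag_ms: float = 1000.0,
    subsample_ms: float = 10.0,
    max_fit_lag_ms: float = 400.0,
    floor: float = 1e-2,
) -> pd.DataFrame:
    """Per-level autocorrelation time constants θ_L by exponential fit.

    For each level, the trial-averaged normalised autocorrelation of the
    prediction is computed, its envelope extracted (magnitude of the analytic
    signal, so the fit tracks the decay of oscillation coherence rather than
    the oscillation itself), subsampled every ``subsample_ms``, and fit with
    ``A·exp(-lag/θ)`` by least squares on the linear-log transform over lags
    up to ``max_fit_lag_ms`` where the envelope exceeds ``floor`` (the
    nonnegativity/noise-floor guard for the log). Signals whose envelope
    collapses within a couple of subsample steps (e.g. white noise) are fit on
    the full-resolution envelope prefix instead. Returns a frame with
    ``level`` (1-based), ``theta_ms`` and the fit's ``r_squared``.
    """
    fs = run.fs
    n_lag = int(round(max_lag_ms * fs / 1000.0))
    step = max(1, int(round(subsample_ms * fs / 1000.0)))
    rows = []
    for lvl, ts in enumerate(run.predictions, start=1):
        ac = autocorrelation(ts.data, n_lag)
        env = np.abs(signal.hilbert(ac))
        lags_ms = np.arange(env.size) / fs * 1000.0
        vals, lags = env[::step], lags_ms[::step]
        ok = (lags <= max_fit_lag_ms) & (vals > floor)
        if ok.sum() < 3:
            # fast-decaying signal: fit the contiguous full-resolution prefix
            k = int(np.argmax(env <= floor)) if np.any(env <= floor) else env.size
            k = max(k, 2)
            vals, lags, ok = env[:k], lags_ms[:k], np.ones(k, dtype=bool)
        slope, intercept = np.polyfit(lags[ok], np.log(vals[ok]), 1)
        fitted = slope * lags[ok] + intercept
        resid = np.log(vals[ok]) - fitted
        ss_tot = np.sum((np.log(vals[ok]) - np.log(vals[ok]).mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
        theta = -1.0 / slope if slope < 0 else np.inf
        rows.append({"level": lvl, "theta_ms": float(theta), "r_squared": float(r2)})
    return pd.DataFrame(rows)
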