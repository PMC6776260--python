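"""Hierarchical predictive-coding network with inter-level communication delays.

The model is a chain of L = 1..N levels. Each level holds a prediction
``y_L(t)`` of the activity below it; the level below only passes up the
residual (prediction error)

    x_L(t) = y_{L-1}(t) - y_L(t - ΔT),            with y_0(t) = input(t),

where ΔT is the inter-level communication delay. Predictions integrate the
delayed residual and relax toward the (delayed) prediction of the level above:

    dy_L/dt = (1/τ)  · x_L(t - ΔT)
            + (1/τ_D) · ( y_{L+1}(t - ΔT) - y_L(t) ),   y_{N+1}(t) = prior(t).

τ is the neuronal integration time constant, τ_D the slower decay / top-down
time constant. With zero prior the second term is a pure decay to rest. The
closed sensorimotor-style loop between two levels has round-trip delay 2ΔT,
which is what makes the system oscillate (see :mod:`pcwaves.analytics`).

Equations are integrated with an explicit forward-Euler scheme at a fixed step
(1 ms by default). All signals are zero for t <= 0 (zero pre-history). Within
a step, all residuals are evaluated from stored history before any prediction
is advanced, so the result does not depend on the order levels are visited.

Delays may be asymmetric: a feedforward delay for residuals traveling up and a
feedback delay for predictions traveling down. The oscillatory behaviour
depends chiefly on their sum, so (16, 8) ms behaves like symmetric 12 ms.

Predictions can optionally be passed through a saturating sigmoid when
transmitted between levels (``nonlinearity="sigmoid"``); the drives are then
rescaled so that they exercise the non-linear range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .signals import TimeSeriesSet
from .synth import NoiseSpec, white_noise

__all__ = [
    "ModelConfig",
    "DriveSignals",
    "SimulationRun",
    "SimulationDiverged",
    "simulate",
    "simulate_trials",
    "apply_nonlinearity",
    "DEFAULT_TWO_LEVEL",
    "DEFAULT_MULTILEVEL",
]


class SimulationDiverged(RuntimeError):
    """Raised when a prediction trace exceeds the overflow guard."""

    def __init__(self, level: int, step: int, value: float):
        self.level = level
        self.step = step
        super().__init__(
            f"simulation diverged at level {level}, step {step} (|y| = {value:.3g}); "
            "reduce dt or check parameters"
        )


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the delay-coupled predictive-coding network.

    ``n_levels`` counts prediction populations ``y_L`` (the sensory drive sits
    below level 1): the classic two-area model is ``n_levels=1`` and the
    seven-channel hierarchy is ``n_levels=7``.

    All times are in milliseconds. ``delta_t`` (and the asymmetric variants)
    must be integer multiples of the integration step ``dt``. ``tau_d < tau``
    would give hierarchically higher processes a faster timescale than lower
    ones, which is implausible; such configs are accepted but flagged by
    :meth:`warnings`.
    """

    n_levels: int = 1
    delta_t: float = 12.0
    tau: float = 17.0
    tau_d: float = 200.0
    dt: float = 1.0
    delta_t_fwd: float | None = None  # feedforward delay; defaults to delta_t
    delta_t_bwd: float | None = None  # feedback delay; defaults to delta_t
    nonlinearity: Literal["linear", "sigmoid"] = "linear"
    sigmoid_gain: float = 1.0
    sigmoid_offset: float = 0.0
    drive_scale: float = 3.0  # drive rescaling in sigmoid mode
    overflow_guard: float = 1e9

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau <= 0 or self.tau_d <= 0:
            raise ValueError("tau and tau_d must be positive")
        for name, value in (
            ("delta_t", self.delta_t),
            ("delta_t_fwd", self.fwd_delay),
            ("delta_t_bwd", self.bwd_delay),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
            steps = value / self.dt
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(
                    f"{name} = {value} ms is not an integer multiple of dt = {self.dt} ms"
                )

    @property
    def fwd_delay(self) -> float:
        return self.delta_t if self.delta_t_fwd is None else self.delta_t_fwd

    @property
    def bwd_delay(self) -> float:
        return self.delta_t if self.delta_t_bwd is None else self.delta_t_bwd

    @property
    def fs(self) -> float:
        """Sampling rate of the integration grid, in Hz."""
        return 1000.0 / self.dt

    def warnings(self) -> list[str]:
        """Physiological-plausibility warnings (non-fatal)."""
        out = []
        if self.tau_d < self.tau:
            out.append(
                f"tau_d ({self.tau_d} ms) < tau ({self.tau} ms): implies a faster "
                "timescale for hierarchically higher processes"
            )
        for name, value in (("delta_t_fwd", self.fwd_delay), ("delta_t_bwd", self.bwd_delay)):
            if not (1.0 <= value <= 50.0):
                out.append(f"{name} = {value} ms is outside the plausible 1-50 ms range")
        return out


# The classic two-area configuration (Fig-style "2-level" model): a sensory
# area encoding the residual plus ONE prediction unit above it, i.e.
# n_levels counts prediction populations. Its closed loop has round-trip
# delay 2*delta_t and rings at ~10 Hz for delta_t=12 ms, tau=17 ms.
DEFAULT_TWO_LEVEL = ModelConfig(n_levels=1, delta_t=12.0, tau=17.0, tau_d=200.0)
# Seven prediction levels, one per simulated EEG channel.
DEFAULT_MULTILEVEL = ModelConfig(n_levels=7, delta_t=12.0, tau=20.0, tau_d=200.0)


@dataclass
class DriveSignals:
    """Sensory input (drives level 1) and top-down prior (drives level N).

    Either may be ``None`` (treated as identically zero), but not both shapes
    may disagree: when both are present they must share trial count, length
    and sampling rate.
    """

    input: TimeSeriesSet | None = None
    prior: TimeSeriesSet | None = None

    def __post_init__(self) -> None:
        if self.input is None and self.prior is None:
            raise ValueError("at least one of input/prior must be provided")
        if self.input is not None and self.prior is not None:
            a, b = self.input, self.prior
            if a.data.shape != b.data.shape or a.fs != b.fs:
                raise ValueError("input and prior must share trial count, length and rate")

    @property
    def reference(self) -> TimeSeriesSet:
        return self.input if self.input is not None else self.prior  # type: ignore[return-value]

    @property
    def n_trials(self) -> int:
        return self.reference.n_trials

    @property
    def n_samples(self) -> int:
        return self.reference.n_samples

    @property
    def fs(self) -> float:
        return self.reference.fs


@dataclass
class SimulationRun:
    """Per-level prediction and residual traces plus the config that made them.

    ``predictions[l]`` and ``residuals[l]`` are (trials, time) arrays for level
    ``l+1`` (index 0 is the lowest level). Prediction signals are the package's
    EEG proxy; residuals are retained because using the first level instead
    gives similar results up to a phase shift.
    """

    config: ModelConfig
    predictions: list[TimeSeriesSet]
    residuals: list[TimeSeriesSet]
    drives: DriveSignals | None = None
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return self.predictions[0].fs

    def prediction_array(self) -> np.ndarray:
        """Stack predictions into a (trials, levels, time) array."""
        return np.stack([p.data for p in self.predictions], axis=1)


def apply_nonlinearity(config: ModelConfig, value):
    """Saturating sigmoid applied to predictions transmitted between levels.

    A logistic rescaled to the range (-1, 1), centered on ``sigmoid_offset``:
    ``f(v) = 2 / (1 + exp(-gain (v - offset))) - 1``. At ``v = offset`` it
    returns the midpoint of its range (0 for the default offset), it is
    monotone increasing, and saturates at ±1. With the default offset the
    zero-drive fixed point of the linear model is preserved.
    """
    v = np.asarray(value, dtype=float)
    # tanh(x/2) is the overflow-safe form of 2/(1 + e^-x) - 1
    out = np.tanh(0.5 * config.sigmoid_gain * (v - config.sigmoid_offset))
    return out if out.ndim else float(out)


def _zero_like(drives: DriveSignals) -> np.ndarray:
    return np.zeros((drives.n_trials, drives.n_samples))


def simulate(config: ModelConfig, drives: DriveSignals) -> SimulationRun:
    """Integrate the network with forward Euler and return all traces.

    The residual at level L is evaluated with the level-L prediction delayed
    by the feedback delay; the prediction update uses the residual delayed by
    the feedforward delay, hence a total loop delay of ΔT_fwd + ΔT_bwd = 2ΔT
    in the symmetric case. Pre-history (t <= 0) is zero everywhere.
    """
    dt = config.dt
    if abs(drives.fs - config.fs) > 1e-9:
        raise ValueError(
            f"drive sampling rate {drives.fs} Hz does not match the integration "
            f"grid {config.fs} Hz (dt = {dt} ms)"
        )
    d_f = int(round(config.fwd_delay / dt))
    d_b = int(round(config.bwd_delay / dt))
    n_tr = drives.n_trials
    n_t = drives.n_samples
    n_lv = config.n_levels

    sigmoid = config.nonlinearity == "sigmoid"
    scale = config.drive_scale if sigmoid else 1.0
    inp = drives.input.data * scale if drives.input is not None else np.zeros((n_tr, n_t))
    pri = drives.prior.data * scale if drives.prior is not None else np.zeros((n_tr, n_t))

    y = np.zeros((n_tr, n_lv, n_t))
    a = dt / config.tau
    b = dt / config.tau_d
    guard = config.overflow_guard

    def tx(arr):
        """Inter-level transmission of predictions (squashed in sigmoid mode)."""
        return apply_nonlinearity(config, arr) if sigmoid else arr

    below = np.empty((n_tr, n_lv))
    above = np.empty((n_tr, n_lv))
    for k in range(n_t - 1):
        kf = k - d_f           # time index of the residual used in the update
        kfb = k - d_f - d_b    # prediction delayed by the full loop
        kb = k - d_b

        # y_{L-1}(k - d_f): the local activity the residual is computed against
        # at the lower site (raw input for level 1); residuals travel up as-is,
        # only predictions traveling down are squashed in sigmoid mode.
        below[:, 0] = inp[:, kf] if kf >= 0 else 0.0
        below[:, 1:] = y[:, :-1, kf] if kf >= 0 else 0.0
        # y_L(k - d_f - d_b), the doubly delayed own prediction inside x_L
        own = tx(y[:, :, kfb]) if kfb >= 0 else np.zeros((n_tr, n_lv))
        x_delayed = below - own
        # y_{L+1}(k - d_b): transmitted predictions, prior at the top
        above[:, :-1] = tx(y[:, 1:, kb]) if kb >= 0 else 0.0
        above[:, -1] = pri[:, kb] if kb >= 0 else 0.0

        y[:, :, k + 1] = y[:, :, k] + a * x_delayed + b * (above - y[:, :, k])

        if not np.all(np.isfinite(y[:, :, k + 1])) or np.any(np.abs(y[:, :, k + 1]) > guard):
            bad = np.abs(y[:, :, k + 1])
            lvl = int(np.unravel_index(np.nanargmax(bad), bad.shape)[1])
            raise SimulationDiverged(lvl + 1, k + 1, float(np.nanmax(bad)))

    # Residuals x_L(k) = y_{L-1}(k) - y_L(k - d_b), reported on the output grid.
    x = np.zeros((n_tr, n_lv, n_t))
    x[:, 0, :] = inp
    x[:, 1:, :] = y[:, :-1, :]
    x[:, :, d_b:] -= tx(y[:, :, : n_t - d_b])

    fs = config.fs
    predictions = [TimeSeriesSet(y[:, l, :], fs) for l in range(n_lv)]
    residuals = [TimeSeriesSet(x[:, l, :], fs) for l in range(n_lv)]
    return SimulationRun(config, predictions, residuals, drives)


def simulate_trials(
    config: ModelConfig,
    duration: float,
    n_trials: int,
    drive_mode: Literal["input", "prior", "both"] = "input",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    burn_in: float = 0.5,
    noise_cutoff_hz: float = 80.0,
) -> tuple[SimulationRun, DriveSignals]:
    """Run white-noise-driven trials and trim the onset transient.

    Generates ``duration + burn_in`` seconds of band-limited white noise per
    trial (independent streams for input and prior when both are requested),
    integrates the network, and returns the final ``duration`` seconds of
    drives and traces so downstream statistics see a stationary regime.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    total = duration + burn_in
    spec = NoiseSpec(duration=total, fs=config.fs, cutoff_hz=noise_cutoff_hz, variance=1.0)

    inp = white_noise(spec, n_trials, rng=rng) if drive_mode in ("input", "both") else None
    pri = white_noise(spec, n_trials, rng=rng) if drive_mode in ("prior", "both") else None
    drives = DriveSignals(input=inp, prior=pri)
    run = simulate(config, drives)

    skip = int(round(burn_in * config.fs))

    def trim(ts: TimeSeriesSet | None) -> TimeSeriesSet | None:
        return None if ts is None else TimeSeriesSet(ts.data[:, skip:], ts.fs)

    trimmed = DriveSignals(input=trim(inp), prior=trim(pri))
    out = SimulationRun(
        config,
        [trim(p) for p in run.predictions],  # type: ignore[misc]
        [trim(r) for r in run.residuals],  # type: ignore[misc]
        trimmed,
        meta={"burn_in_s": burn_in, "drive_mode": drive_mode, "duration_s": duration},
    )
    return out, trimmed


def with_params(config: ModelConfig, **kwargs) -> ModelConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
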