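"""Shared in-memory containers for trial sets and space-time maps.

Two containers recur throughout the package:

* :class:`TimeSeriesSet` — a stack of trials of a scalar signal sampled at a
  fixed rate (stimulus sequences, top-down priors, per-level predictions or
  residuals).
* :class:`SpaceTimeMap` — an ordered channels-by-time matrix, the object the
  traveling-wave statistic consumes. Rows are ordered from low to high along
  the hierarchy (for the model) or from posterior to anterior (for EEG
  montages such as Oz ... Fz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeriesSet", "SpaceTimeMap"]


@dataclass
class TimeSeriesSet:
    """Trials x time array of a scalar signal with its sampling rate.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_samples)``. A 1-D array is promoted to a
        single trial.
    fs
        Sampling rate in Hz.
    """

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[None, :]
        if self.data.ndim != 2:
            raise ValueError(f"expected (trials, time) array, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def __len__(self) -> int:
        return self.n_trials


@dataclass
class SpaceTimeMap:
    """Ordered channels x time matrix with sampling rate.

    Row order is meaningful: index 0 is the lowest hierarchical level (or most
    posterior electrode) and the last row is the highest (most anterior). The
    forward/backward wave statistic is defined relative to this ordering.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] | None = None
    window_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"expected (channels, time) array, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("a space-time map needs at least 2 channels")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match the number of rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def reversed_channels(self) -> "SpaceTimeMap":
        """Return a copy with the channel (row) order reversed."""
        names = list(self.channel_names[::-1]) if self.channel_names else None
        return SpaceTimeMap(self.data[::-1].copy(), self.fs, names, self.window_id, dict(self.meta))
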