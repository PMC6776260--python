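"""Simulator contract: zero-drive fixed point, Euler-oracle equality,
linearity, delay handling, divergence reporting and the sigmoid variant."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_array_equal

import pcwaves as pw
from pcwaves import (
    DriveSignals,
    ModelConfig,
    SimulationDiverged,
    TimeSeriesSet,
    apply_nonlinearity,
    simulate,
)

FS = 1000.0


def _drive(data):
    return DriveSignals(input=TimeSeriesSet(np.asarray(data, dtype=float), FS))


def test_zero_drive_zero_history_stays_at_rest():
    cfg = ModelConfig(n_levels=3, delta_t=12.0, tau=17.0, tau_d=200.0)
    run = simulate(cfg, _drive(np.zeros((2, 400))))
    for ts in run.predictions + run.residuals:
        assert not ts.data.any()


def _oracle_euler_two_levels(cfg: ModelConfig, inp: np.ndarray) -> np.ndarray:
    """Independent scalar forward-Euler loop for a 2-prediction-level chain.

    Written directly from the update rule: residuals from stored history,
    then predictions, same floating-point expression shape as the simulator.
    """
    d = int(round(cfg.delta_t / cfg.dt))
    n = inp.size
    a = cfg.dt / cfg.tau
    b = cfg.dt / cfg.tau_d
    y1 = np.zeros(n)
    y2 = np.zeros(n)

    def at(arr, k):
        return arr[k] if k >= 0 else 0.0

    for k in range(n - 1):
        x1_del = at(inp, k - d) - at(y1, k - 2 * d)
        x2_del = at(y1, k - d) - at(y2, k - 2 * d)
        y1[k + 1] = y1[k] + a * x1_del + b * (at(y2, k - d) - y1[k])
        y2[k + 1] = y2[k] + a * x2_del + b * (0.0 - y2[k])
    return np.stack([y1, y2])


def test_matches_independent_euler_oracle_bit_for_bit():
    cfg = ModelConfig(n_levels=2, delta_t=12.0, tau=17.0, tau_d=200.0)
    inp = np.zeros(500)
    inp[0:] = 1.0  # unit step drive
    run = simulate(cfg, _drive(inp[None, :]))
    expected = _oracle_euler_two_levels(cfg, inp)
    assert_array_equal(run.predictions[0].data[0], expected[0])
    assert_array_equal(run.predictions[1].data[0], expected[1])


def test_residuals_follow_their_definition():
    cfg = ModelConfig(n_levels=2, delta_t=10.0, tau=17.0, tau_d=200.0)
    rng = np.random.default_rng(0)
    inp = rng.normal(size=(1, 300))
    run = simulate(cfg, _drive(inp))
    d = 10
    y1 = run.predictions[0].data[0]
    x1 = run.residuals[0].data[0]
    delayed = np.concatenate([np.zeros(d), y1[:-d]])
    np.testing.assert_allclose(x1, inp[0] - delayed, atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=10)
@given(scale=st.floats(min_value=0.1, max_value=50.0))
def test_linear_mode_is_homogeneous(scale):
    cfg = ModelConfig(n_levels=2, delta_t=8.0, tau=17.0, tau_d=200.0)
    rng = np.random.default_rng(7)
    inp = rng.normal(size=(1, 200))
    base = simulate(cfg, _drive(inp)).predictions[1].data
    scaled = simulate(cfg, _drive(scale * inp)).predictions[1].data
    np.testing.assert_allclose(scaled, scale * base, rtol=1e-10, atol=1e-12)


def test_superposition_over_independent_drives():
    cfg = ModelConfig(n_levels=2, delta_t=8.0, tau=20.0, tau_d=200.0)
    rng = np.random.default_rng(3)
    a = rng.normal(size=(1, 250))
    b = rng.normal(size=(1, 250))
    ya = simulate(cfg, _drive(a)).predictions[1].data
    yb = simulate(cfg, _drive(b)).predictions[1].data
    yab = simulate(cfg, _drive(a + b)).predictions[1].data
    np.testing.assert_allclose(yab, ya + yb, rtol=1e-9, atol=1e-12)


def test_non_multiple_delay_is_rejected():
    with pytest.raises(ValueError, match="integer multiple"):
        ModelConfig(delta_t=12.5, dt=1.0)


def test_divergence_is_flagged_with_level_and_step():
    cfg = ModelConfig(n_levels=2, delta_t=12.0, tau=2.0, tau_d=200.0, overflow_guard=1e3)
    rng = np.random.default_rng(1)
    with pytest.raises(SimulationDiverged, match="level"):
        simulate(cfg, _drive(rng.normal(size=(1, 3000))))


def test_implausible_tau_d_is_flagged_not_fatal():
    cfg = ModelConfig(n_levels=2, delta_t=12.0, tau=30.0, tau_d=20.0)
    assert any("tau_d" in w for w in cfg.warnings())


def test_asymmetric_delays_equivalent_to_their_mean():
    """16/8 ms split delays ring at the same frequency as symmetric 12 ms."""
    sym = ModelConfig(n_levels=1, delta_t=12.0, tau=17.0)
    asym = ModelConfig(n_levels=1, delta_t=12.0, delta_t_fwd=16.0, delta_t_bwd=8.0, tau=17.0)
    peaks = []
    for cfg in (sym, asym):
        run, drives = pw.simulate_trials(cfg, 3.0, 60, "input", seed=11)
        irf = pw.crosscorrelate(run.predictions[-1], drives.input)
        peaks.append(pw.irf_spectrum(irf).peak_frequency_hz)
    bin_hz = FS / irf.n_lags
    assert abs(peaks[0] - peaks[1]) <= bin_hz + 1e-9


class TestSigmoid:
    def test_midpoint_at_offset(self):
        cfg = ModelConfig(nonlinearity="sigmoid", sigmoid_offset=0.7)
        assert apply_nonlinearity(cfg, 0.7) == pytest.approx(0.0, abs=1e-12)

    def test_saturation_and_monotonicity(self):
        cfg = ModelConfig(nonlinearity="sigmoid")
        assert apply_nonlinearity(cfg, -40.0) == pytest.approx(-1.0, abs=1e-12)
        assert apply_nonlinearity(cfg, 40.0) == pytest.approx(1.0, abs=1e-12)
        v = np.linspace(-5, 5, 101)
        out = apply_nonlinearity(cfg, v)
        assert np.all(np.diff(out) > 0)

    def test_sigmoid_multilevel_keeps_forward_wave_sign(self):
        cfg = ModelConfig(n_levels=7, delta_t=12.0, tau=20.0, tau_d=200.0,
                          nonlinearity="sigmoid")
        run, _ = pw.simulate_trials(cfg, 6.0, 10, "input", seed=5)
        maps = pw.maps_from_trials(run.predictions)
        mean_lr = np.mean([pw.quadrant_stat(m).log_ratio for m in maps])
        assert mean_lr > 0
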