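"""Closed-form and numerical analysis of the simplified two-level delay equation.

When the slow top-down term is negligible (τ_D >> τ) and the drive integrates
to zero, the two-level network reduces to a scalar delay differential equation

    dy/dt = -(1/τ) · y(t - 2ΔT),

whose exponential ansatz ``y = exp(α t)`` yields the transcendental
characteristic equation

    -α τ = exp(-2 α ΔT).

A purely oscillatory solution (α = iω) requires cos(2ωΔT) = 0 and ωτ = 1
simultaneously, giving the lowest-frequency branch

    ω = 2π / (8 ΔT)          (period = 8 ΔT),
    τ = 8 ΔT / (2π) = (4/π) ΔT ≈ 1.2732 ΔT.

So a 12-ms inter-level delay rings at ~10.4 Hz, and delays of 10-15 ms cover
the alpha band. This module exposes those closed forms plus a numeric root
finder for the full complex characteristic equation, used both to classify
(τ, ΔT) regimes and as an independent check on the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "CharacteristicSolution",
    "oscillation_frequency",
    "oscillation_period_ratio",
    "optimal_tau",
    "optimal_tau_numeric",
    "characteristic_roots",
    "dominant_root",
]

_NEUTRAL_TOL = 1e-8


@dataclass(frozen=True)
class CharacteristicSolution:
    """One root α = alpha_real + i·omega of ``-ατ = exp(-2αΔT)``.

    ``omega`` is in rad/ms (non-negative by convention; roots come in
    conjugate pairs), ``frequency_hz`` its rescaling to Hz. ``regime`` is
    'oscillatory-neutral' (|Re α| ≈ 0, ω > 0), 'damped-oscillatory'
    (Re α < 0, ω > 0), 'unstable-oscillatory' (Re α > 0, ω > 0) or
    'non-oscillatory' (ω ≈ 0).
    """

    alpha_real: float
    omega: float
    tau_over_deltat: float

    @property
    def frequency_hz(self) -> float:
        return 1000.0 * self.omega / (2.0 * np.pi)

    @property
    def regime(self) -> str:
        if self.omega < _NEUTRAL_TOL:
            return "non-oscillatory"
        if abs(self.alpha_real) < _NEUTRAL_TOL:
            return "oscillatory-neutral"
        return "damped-oscillatory" if self.alpha_real < 0 else "unstable-oscillatory"


def oscillation_frequency(delta_t: float) -> float:
    """Frequency (Hz) of the pure-oscillation branch: period = 8·ΔT.

    ``delta_t`` is in ms; the lowest-frequency oscillatory solution has
    ω = 2π/(8ΔT), i.e. 1000/(8·ΔT) Hz.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return 1000.0 / (8.0 * delta_t)


def oscillation_period_ratio(delta_t: float = 12.0) -> float:
    """Oscillation period in units of ΔT, from the real-part condition.

    Solves cos(2ωΔT) = 0 numerically for the lowest positive ω and returns
    (2π/ω)/ΔT; equals 8 for every ΔT.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    # lowest positive root of cos(2 w dT) lies in (0, pi/(2 dT))
    f = lambda w: np.cos(2.0 * w * delta_t)
    w = optimize.brentq(f, 1e-9, np.pi / (2.0 * delta_t) + 1e-9, xtol=1e-15)
    return (2.0 * np.pi / w) / delta_t


def optimal_tau(delta_t: float) -> float:
    """τ (ms) giving a purely oscillatory solution: τ = 8ΔT/(2π) ≈ 1.2732·ΔT."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return 8.0 * delta_t / (2.0 * np.pi)


def _char_residual(alpha: complex, delta_t: float, tau: float) -> complex:
    return alpha * tau + np.exp(-2.0 * alpha * delta_t)


def _solve_root(alpha0: complex, delta_t: float, tau: float) -> complex | None:
    def f(v):
        r = _char_residual(v[0] + 1j * v[1], delta_t, tau)
        return [r.real, r.imag]

    sol = optimize.root(f, [alpha0.real, alpha0.imag], tol=1e-13)
    if not sol.success:
        return None
    root = sol.x[0] + 1j * sol.x[1]
    if abs(_char_residual(root, delta_t, tau)) > 1e-8:
        return None
    return root


def characteristic_roots(
    delta_t: float, tau: float, n_branches: int = 3
) -> list[CharacteristicSolution]:
    """Dominant complex roots of ``-ατ = exp(-2αΔT)`` by numeric root finding.

    Seeds the search on the k = 0..n_branches-1 branches of the imaginary-part
    condition (ω near (2k+1)·π/(4ΔT)) plus the real axis, polishes each with a
    2-D Newton solve, deduplicates, and returns roots sorted by descending real
    part (the most slowly decaying — dominant — first). Only ω >= 0
    representatives are kept; conjugates are implied.
    """
    if delta_t <= 0 or tau <= 0:
        raise ValueError("delta_t and tau must be positive")
    seeds: list[complex] = [complex(-1.0 / tau, 0.0)]
    for k in range(n_branches):
        w = (2 * k + 1) * np.pi / (4.0 * delta_t)
        seeds.append(complex(0.0, w))
        seeds.append(complex(-0.5 / tau, w))

    roots: list[complex] = []
    for s in seeds:
        r = _solve_root(s, delta_t, tau)
        if r is None:
            continue
        if r.imag < -1e-12:
            r = r.conjugate()
        if all(abs(r - q) > 1e-6 * max(1.0, abs(q)) for q in roots):
            roots.append(r)
    if not roots:
        raise RuntimeError(
            f"characteristic root search failed for delta_t={delta_t}, tau={tau} "
            f"(searched {len(seeds)} seeds around Im(alpha) in (0, {n_branches}*pi/(2 delta_t)])"
        )
    roots.sort(key=lambda r: -r.real)
    return [
        CharacteristicSolution(r.real, max(r.imag, 0.0), tau / delta_t) for r in roots
    ]


def dominant_root(delta_t: float, tau: float) -> CharacteristicSolution:
    """The root with the largest real part (slowest decay)."""
    return characteristic_roots(delta_t, tau)[0]


def optimal_tau_numeric(delta_t: float, bracket: tuple[float, float] = (0.5, 4.0)) -> float:
    """τ at which the dominant root crosses the imaginary axis, found numerically.

    Scans Re(α_dominant) as a function of τ/ΔT over ``bracket`` and solves for
    the zero crossing with Brent's method. Independent of :func:`optimal_tau`'s
    closed form; used to cross-check it.
    """

    def re_dominant(ratio: float) -> float:
        return dominant_root(delta_t, ratio * delta_t).alpha_real

    lo, hi = bracket
    ratio = optimize.brentq(re_dominant, lo, hi, xtol=1e-12)
    return ratio * delta_t
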