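"""Where does the model oscillate? Ask the characteristic equation.

The reduced two-area loop obeys dy/dt = -y(t - 2*deltaT)/tau. Exponential
solutions exp(alpha*t) satisfy -alpha*tau = exp(-2*alpha*deltaT); the sign of
Re(alpha) for the dominant root classifies each (tau, deltaT) cell as damped,
neutral (pure oscillation) or unstable, and Im(alpha) gives the frequency.
"""

from pcwaves import characteristic_roots, optimal_tau, optimal_tau_numeric, oscillation_frequency

delta_t = 12.0
print(f"delay {delta_t} ms -> oscillation at {oscillation_frequency(delta_t):.2f} Hz (period 8*deltaT)")
print(f"neutral-oscillation tau: closed form {optimal_tau(delta_t):.4f} ms, "
      f"numeric root finder {optimal_tau_numeric(delta_t):.4f} ms")

for tau in (10.0, optimal_tau(delta_t), 17.0, 100.0):
    root = characteristic_roots(delta_t, tau)[0]
    print(f"tau = {tau:7.3f} ms: Re(alpha) = {root.alpha_real:+.5f}/ms, "
          f"f = {root.frequency_hz:6.2f} Hz  [{root.regime}]")
print("-> oscillations live just above tau = 1.27 * deltaT; biologically")
print("   plausible (tau, deltaT) values land squarely in the alpha band.")
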