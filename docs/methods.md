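# Methods

## Model

The network is a chain of `n_levels` prediction populations `y_L(t)` over a
sensory stage. The level below each `y_L` transmits only the prediction error
`x_L(t) = y_{L-1}(t) − y_L(t − ΔT)` (with `y_0 = input`), and predictions are
updated by the delayed error plus a relaxation toward the delayed prediction
of the level above (the top level relaxes toward an external prior, or
toward zero):

```
dy_L/dt = x_L(t − ΔT)/τ + (y_{L+1}(t − ΔT) − y_L(t))/τ_D
```

`n_levels` counts prediction populations: the classic two-area model (sensory
relay + one cortical area) is `n_levels=1`, and the seven-channel hierarchy
used for wave analyses is `n_levels=7`. All signals are in arbitrary units —
the drive is unit-variance by convention and every statistic in the package
is invariant to its overall scale.

Parameters, all in milliseconds:

| parameter | default | meaning |
|---|---|---|
| `delta_t` | 12 | inter-level conduction delay; sets the period (8·ΔT) |
| `tau` | 17 (two-area), 20 (multilevel) | integration constant weighting the residual |
| `tau_d` | 200 | top-down/decay constant; must exceed τ for plausible hierarchies |
| `dt` | 1 | forward-Euler step |

Defaults are the physiological values used throughout the original analyses
of this model family: conduction delays of 10–15 ms and membrane constants of
15–25 ms put the oscillation in the alpha band. Asymmetric delays are
supported (`delta_t_fwd`, `delta_t_bwd`); dynamics depend chiefly on their
sum, so 16/8 ms behaves like symmetric 12 ms.

Numerical scheme: explicit forward Euler at `dt = 1 ms` (configurable), with
all residuals evaluated from stored history before any prediction is advanced
(Jacobi update), so results do not depend on the order levels are visited.
Pre-history is zero everywhere; delays must be integer multiples of `dt` and
are rejected otherwise. Any trace exceeding `overflow_guard` (default 1e9)
raises an error naming the level and step — the linear system is genuinely
unstable for τ below ≈1.27·ΔT, which is a property of the model, not of the
integrator. Trial helpers simulate `duration + burn_in` seconds (burn-in
0.5 s by default) and return the final `duration` seconds of both drives and
traces, so statistics see the stationary regime and a 6-s trial yields 11
one-second analysis windows.

Sigmoid variant: predictions transmitted between levels can be squashed by a
logistic rescaled to (−1, 1), `tanh(gain·(v − offset)/2)`, with the drive
rescaled (±3 by default) to exercise the nonlinear range. The zero fixed
point is preserved, and wave directions match the linear system.

## Analytics

Dropping the τ_D term (valid for τ_D ≫ τ) and merging the two-area equations
gives `dy/dt = −y(t − 2ΔT)/τ`. For `y = e^{αt}` the characteristic equation
is `−ατ = e^{−2αΔT}`. A pure oscillation (α = iω) requires `cos(2ωΔT) = 0`
and `ωτ = 1`, giving ω = 2π/(8ΔT) on the lowest branch and τ = (8/2π)ΔT.
`characteristic_roots` polishes complex roots with a 2-D Newton solve seeded
on the low-order branches of the imaginary-part condition plus the real axis,
deduplicates, and reports all roots sorted by real part rather than choosing
among coexisting damped and neutral branches. `optimal_tau_numeric` brackets
the dominant root's real part in τ/ΔT ∈ [0.5, 4] and solves the zero crossing
by Brent's method; it reproduces the closed form to 1e−9 and serves as the
independent check on it.

## IRF estimation

The impulse response is the lag-wise cross-correlation of the drive (leading)
with a response, mean-centered per trial, averaged over trials, with each lag
divided by its valid overlap length (no zero-padding bias). The default
normalisation is the Pearson coefficient per lag — the conventional
perceptual-echo estimator — which also puts channels of very different
response amplitude on a common scale; `unit-drive` (covariance over drive
variance) and raw covariance are options. Spectra are amplitude spectra of
the mean-removed IRF; the peak is the maximum at or above a 2-Hz floor
(skipping DC leakage). With the 1-s IRF support the frequency resolution is
≈1 Hz, so a 10.42-Hz echo reports as the 10-Hz bin.

## Wave statistic

Maps are channels × time with rows ordered low-to-high (hierarchy, or
posterior-to-anterior). Rows are mean-centered; the 2D spectrum is the
temporal rFFT followed by a channel-axis FFT; the temporal DC column is
excluded. With this orientation a forward wave `cos(2πft − 2πκc)`, κ > 0,
peaks at negative spatial DFT frequency and positive temporal frequency, so
the FW quadrant is (spatial < 0, temporal > 0) and BW its mirror. The
zero-spatial-frequency midline row belongs to both quadrants, which makes a
standing wave score exactly zero; for even channel counts the spatial Nyquist
row (its own mirror) is excluded so the statistic stays exactly antisymmetric
under channel reversal. The log ratio uses the natural log.

Surrogate test: for every map, fresh random channel permutations (identity
excluded) are drawn and their log ratios pooled into one null sample. Row
permutation commutes with the temporal FFT, so the null costs one channel-axis
FFT per permutation. Real and null samples are histogrammed on 50 shared
equal-width bins; the significant proportions are the positive part of the
(real − null) density difference summed over positive (FW) and negative (BW)
bins, and a two-sample KS statistic compares real against the pooled null.
The histogram-difference estimator is positively biased for small samples
(~5% at 400 epochs, <4% at the ~2200 epochs the sliding-window analyses
produce); a per-epoch percentile rule against the epoch's own shuffle null is
available as a cross-check (`SurrogateEnsemble.real`/`null` expose the raw
samples).

Wave speed is (peak temporal frequency / |peak spatial frequency|) × channel
spacing, read from the dominant off-axis spectral peak; standing waves return
`inf` rather than a number. Source mixing replaces each channel by a
distance-weighted average (weights 1, 0.8, 0.6, 0.4 by hierarchical distance,
truncated and renormalised at the edges), emulating scalp blurring: the
dominant spatial frequency drops, so apparent speed rises. Note that for
maps with strong per-row amplitude gradients (the raw model predictions grow
several-fold per level) mixing drives the quadrant maxima onto the midline
and the log ratio toward zero; the speed estimate is unaffected because it
ignores the midline.

## Timescale characterization

Per level, the trial-averaged normalised autocorrelation of the prediction is
computed by FFT; its envelope (magnitude of the analytic signal) is
subsampled every 10 ms and fit with `A·e^{−lag/θ}` by least squares on the
log, over lags up to 400 ms where the envelope exceeds a 0.01 noise floor.
The envelope is used so the fit tracks the decay of oscillation coherence
rather than the alpha cycle itself; signals whose envelope collapses within a
couple of subsample steps (white noise) are fit on the full-resolution
prefix instead. On the default input-driven run θ grows monotonically with
level from ≈85 to ≈190 ms (Spearman ρ ≈ 0.96) even though every level shares
the same τ — the network, not the neuron, sets the timescale. The absolute
values depend on the fit window; longer windows admit envelope beating that
breaks monotonicity, which is why 400 ms is the default.

## Synthetic data

White-noise drives are built in the frequency domain — unit-magnitude
coefficients with uniform random phases up to the cutoff (80 Hz by default,
matching a 160-Hz stimulus refresh), zero above, zero DC — so the flat
spectrum is exact by construction; trials are rescaled to exactly unit
variance. Plane-wave fixtures `cos(2πft − 2πκc) + noise` carry their
generating parameters in metadata, so ground-truth direction and speed are
always recoverable. These generators emulate the *statistics* the analyses
rely on (flat spectra, known propagation), not real EEG: no 1/f background,
no artifacts, no volume conduction beyond the explicit mixing kernel, and no
inter-subject variability — passing tests demonstrate the machinery, not
human-data effect sizes. Published human percentages (56.6 / 36.5 / 41.1%)
require the original recordings and are out of scope here.

## Scales used by the bundled analyses

The full pipeline (`pcwaves.pipeline.wave_direction_report`, also behind
`scripts/acceptance.py`) uses the study-scale conditions: 200 trials of 6 s,
1-s windows with 500-ms overlap (2200 EEG epochs and 200 per-trial IRF maps
per condition), and 1000 level shuffles per map; it completes in ~2.5 minutes
on one core. Examples and unit tests use 8–60 trials and 150–300 shuffles,
which reproduce the direction pattern with wider sampling error. The τ_D
sweep default is 20–200 ms (stride 5, 20 single-trial replicates per value);
the two-area regime grid runs 100–200 trials per cell.

## Known limitations

* Backward (prior-driven) waves in raw prediction maps are weaker than
  forward ones (mean log ratio ≈ −0.16 vs +0.43): the downward coupling gain
  is 1/τ_D against 1/τ upward, so amplitude decays along the direction of
  travel. Backward-significant EEG proportions (~67%) are correspondingly
  lower than forward ones (~80%). Row-normalising maps symmetrizes the two
  directions but is deliberately not applied to the statistics.
* The model is a rate chain without laminar structure, spiking, conductances,
  retinotopy or thalamic gating; it speaks to timing and direction, not to
  amplitude topographies.
* The quadrant-maximum statistic sees only the single strongest component per
  direction; mixtures of simultaneous FW and BW waves at different
  frequencies are summarised by whichever is stronger.
* No preprocessing (filtering, re-referencing, artifact handling) is
  provided; recordings are assumed clean, uniformly sampled matrices.
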