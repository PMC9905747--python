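# Methods

This note documents the models, estimators, calibrations and design
choices behind `spiketransfer`, and what its synthetic conditions do and do
not establish about real data.

## Network model

**Populations.** 300 excitatory (E) and 75 inhibitory (I) hidden units plus
3 LIF output units. Inputs are injected as currents into E units only; unit
*i* receives `Σ_j ff[i,j]·x_j(t)`. Output units integrate the decoder-
weighted E spike trains; their membrane voltage is the analog readout. They
are LIF regardless of the hidden-layer model and may occasionally spike —
the recorded trace includes reset transients.

**Dynamics.** Forward Euler at dt = 0.1 ms (the stimulus resolution), no
adaptive stepping. LIF: `C dv/dt = −gL(v−EL) + (g_e−g_i)·V_unit + I_ext`.
Synapses have no driving force; a conductance is converted to a current by
multiplication with one volt, decays with τ = 5 ms (both E and I; this
matches the 50-step × 0.1 ms filter used when the reference connectivity
was trained) and jumps by the delayed presynaptic weight. Spikes in
distinct units within one step are all delivered. AdEx adds
`gL·ΔT·exp((v−VT)/ΔT)` and subtracts an adaptation current with
`τ_w dw/dt = a(v−EL) − w`, `w += b` at spikes; spike detection happens at a
cut voltage `VT + 5ΔT`, where the exponential argument is clamped so Euler
steps stay finite. After any spike the unit is held at `V_reset` (default:
EL; the source work leaves the reset unstated) for a refractory period of
2 ms (also unstated there; 2 ms puts the saturation ceiling near the
~300 Hz regime where transfer degrades). Delays are per-pathway: one shared
EE/EI/IE/II value and a fixed E→output value, both rounded to whole steps;
delivery lands exactly delay/dt steps after the spike.

**Unit classes.** `Comrade`: one membrane parameter set for E, I and output
units — C = 125 pF, gL = 4 nS (τ_m = 31.25 ms), EL = −70 mV, VT = −50 mV —
chosen inside the published search ranges with the output constraint
τ_out = 31.25 ms (C = 125 pF at gL = 4 nS) fixed. `Bacon`:
literature-flavoured values (regular-spiking pyramidal E: 90 pF/5 nS;
fast basket-like I: 60 pF/12 nS), same outputs as Comrade. `HiFi`: Comrade
with output gL = 40 nS and E→output delay 1 ms (τ_out = 3.125 ms). The
original start-point tables are not public; these presets are this
package's own choices and every field is overridable. "Identical E and I
values" for Comrade refers to the LIF membrane set; under AdEx the E and I
populations deliberately differ (adapting E: a = 0, b = 5 nA, τ_w = 500 ms;
fast-spiking-like I: ΔT = 0.5 mV, a = 0, b = 1 nA, τ_w = 200 ms). The b
values are far above the biological pA scale because the network's current
scale is set by the 10⁻⁷ weight scaling, not by physiology; they are tuned
so the AdEx network fires at roughly a quarter of the LIF rate (see
Calibration).

## Stand-in connectivity

The trained weights of the reference spike-coding network are not
reproducible here (the learning rules live in external Matlab code), so the
default connectivity is an analytic surrogate built on the structure of the
spike-coding optimum:

- `ff` — standard-normal entries normalized so the **global** sum equals
  one (the literal reading of the training convention; per-row
  normalization is available as a switch). A side effect worth knowing: the
  global sum of 900 standard normals is itself random, so the effective
  input gain varies severalfold between connectivity seeds, and so do
  network firing rates.
- `e_out = 3·10⁻⁸ · ffᵀ` — in the optimal solution the linear decoder is
  proportional to the feedforward weights.
- Recurrent pathways through a low-rank inhibitory relay: draw B
  (75 × n_in) with unit-norm rows and set `ei = c_ei·[B ffᵀ]₊`,
  `ie = c_ie·[ff Bᵀ]₊`, `ii = c_ii·[B Bᵀ]₊`, EE autapse-only (0.02 on the
  diagonal, the reset analog). The ideal recurrent interaction `ff ffᵀ` has
  rank ≤ n_in, so the 75-unit relay can realize it; rectification enforces
  pathway polarity. Measured over 10 seeds, after an optimal scalar gain
  the relay product `ie·ei` stays within a 0.5 relative Frobenius error of
  `[ff ffᵀ]₊` (0.25 without rectification); the residual gain is absorbed
  by the calibrated c-constants.
- `build_initial_ei` reproduces the sparse pre-training state (EI: 4 × 0.5
  per I unit; IE: 4 × 0.15; II autapses 0.5) for the untrained control, and
  `load_weights` accepts externally trained matrices in the documented HDF5
  layout.

All pathways except E→output are scaled by 10⁻⁷ into the
nanosiemens-equivalent range; maximum synaptic increments land around
10⁻⁷ S (EI, before the relay gains) down to ~10⁻⁹ S, i.e. the hundreds-of-
nanosiemens to nanosiemens band. Permutation controls shuffle the
post-synaptic target (row) index within each recurrent pathway — one
bijection per pathway, so each source's outgoing weight multiset is
preserved exactly — and the full permutation additionally shuffles `ff`
rows and `e_out` columns, destroying the drive/readout alignment.

## Stimuli

Independent Gaussian white-noise channels (std = `amplitude`) convolved
with a Gaussian kernel (σ = 3 ms default) using reflective padding;
smoothing shrinks the variance by the kernel energy factor
(≈ 1/(2σ√π/dt) ≈ 1/106 at the defaults) and is deliberately not
renormalized. One master seed spawns per-channel child streams. Sinusoids
and constant steps serve the pass-band scan and f–I curves. The standard
protocol is 2 s at 0.1 ms with 200 ms trimmed from each end → 16,000
analysis samples.

## Metrics

**Latency.** Argmax of the plain (signed, unnormalized) cross-correlation,
restricted to nonnegative lags, ties to the smallest lag. An inverted copy
therefore does *not* map back to its delay — intended behavior, matched to
the definition.

**Coherence.** Welch estimates with 3,200-sample segments (native
resolution exactly 3.125 Hz at 10 kHz), 50 % overlap, ≥ 4 segments
required; the DC bin is dropped (degenerate after per-segment detrending)
and values are linearly interpolated onto the 0–100 Hz grid at 3 Hz steps,
the grid mean being the scalar metric. Note one estimator property: a
within-segment delay d carries an intrinsic bias ≈ (1 − d/nperseg)², so
even an exact delayed copy scores slightly below 1.

**Granger causality.** Both series are decimated by 40 (no anti-alias
filter — plain sample-keeping, matching the stated procedure; a filtered
mode exists but is off by default) and first-differenced (400 kept
observations → 399 transitions). The output's own lag order is selected by
AIC over 1..25 on a common sample; the input block always spans the full
100 ms cap (25 lags at 250 Hz). This split is deliberate: an output driven
purely by lagged input is itself nearly white, so a selection criterion
applied to the tested block either truncates below the transfer latency
(losing the coupling entirely) or picks the best-fitting noise lags
(inflating the test). With the input span fixed a priori the
likelihood-ratio null is calibrated — measured 6.0 % rejections at
α = 0.05 over 200 independent null pairs — while a lag-2 coupling of 0.8
is recovered to ±0.01 at n = 400. `F = ln(var(v)/var(u))` with the p-value
from `n·F` against χ²(25); the bits value re-bases the same ratio to log2
(taking log2 of the already-logged F would be negative or undefined for
F < 1 and would break the factor-two relation to continuous transfer
entropy).

**Transfer entropy.** The input is first shifted by its best latency (so
`x_p` lines up with `y_t`), both sequences are decimated and differenced,
then quantized into equal-width bins over each sequence's own observed
range (edges recorded). Plug-in conditional entropies with 0·log 0 = 0;
k = l = 1 only. The bin count follows `n = (N/5)^(1/(k+l+1))` — about five
expected observations per cell of the n³ histogram — giving 4 bins at the
standard N = 400, clamped below at 2.

**Reconstruction error.** Target = leaky-integrated input (Euler first-
order low-pass, τ equal to the output units' membrane time constant:
31.25 ms for Comrade/Bacon, 3.125 ms for HiFi, X(0) = 0); target and output
are min-max scaled to [−1, 1] (a zero-range trace maps to zeros) and
compared as `Var(target − output)/Var(target)`, numerators and denominators
summed over channels in the multichannel form. A silent network scores
exactly 1; delayed or distorted outputs can exceed 1 — on 3 ms-smoothed
noise a delayed copy of the target passes 1 at a few tens of ms.

**Degenerate pairs.** Zero-variance outputs are flagged missing (NaN) for
coherence/GC/TE and score RE = 1 naturally; NaNs never win classification.

## Classification and statistics

Row-wise argbest per metric matrix (ties to the lowest index, logged);
confusion counts over iterations; exact binomial right-tail p-value at
chance 1/j; Bonferroni correction over the grid size of the search;
percentile bootstrap (10,000 resamples, resampling iterations rather than
pooled trials) for the accuracy CI.

## Parameter searches

2-D grids (inhibitory × excitatory) for C, gL, EL, VT over the published
ranges; 1-D for the shared recurrent delay with the E→output delay pinned
(3 ms Comrade/Bacon, 1 ms HiFi). One connectivity per iteration seed is
shared by all grid points, so metric differences across the grid reflect
physiology only; noise is independent per iteration. Failed points
(numerical blow-up) are recorded with a status flag and excluded from
aggregates, never silently dropped. Firing-rate binning uses 10 equal-width
bins over the observed excitatory-rate range; empty bins are absent from
the output.

## Calibration (fixed once, then frozen)

The stimulus amplitude, relay gains and delay start point are not published
quantities. They were calibrated jointly against the reported operating
bands and then frozen as package defaults:

- amplitude 15.0 (pre-smoothing std, model current units), c_ei = 1.0,
  c_ie = 0.5, c_ii = 0.2, recurrent delay 0.5 ms (the bottom of the
  published 0.5–25 ms search range; the tight loop is what lets the relay
  cancel common-mode drive before it drifts the readout into saturation);
- measured at these defaults: Comrade LIF excitatory rate 8.87 Hz
  (seed-averaged; inhibitory slightly higher), AdEx 2.29 Hz, and correct
  coherence- and Granger-winner matrices in 40/40 independent
  connectivity × noise draws.

`scripts/calibrate.py` reruns the sweep.

## What the synthetic conditions show — and what they do not

The generator emulates the study's stimulus statistics (three independent
3 ms-smoothed Gaussian channels, 2 s at 0.1 ms) and the network its
architecture, scalings and delays. The connectivity, however, is an
analytic surrogate, not the trained optimum: absolute metric levels
(coherence ≈ 0.3–0.6 on the matching diagonal at the start point) sit well
below what a trained decoder achieves, reconstruction is correspondingly
coarse, and quantities that depend on the exact trained weights (e.g. a
specific minimum RE for HiFi, or TE-based accuracy at a particular VT
pair) are out of reach. Passing tests therefore establish the correctness
of the estimators, statistics and search machinery, and the qualitative
operating regime (rate bands, rate–information coupling, permutation
collapse, robust Coh/GC classification) — not quantitative agreement of
every surface with the original trained network, and not behavior of
biological tissue.

## Numerical details and edge cases

- Euler decay factors `1 − dt/τ` throughout (consistent with the stated
  integration scheme); halving dt changes single-unit rates by < 2 %.
- Non-finite membrane state aborts the simulation with the offending step
  reported (checked every 256 steps and at the end).
- Refractoriness guarantees ISI > t_ref by construction; asserted in tests.
- Constant inputs to correlation/Granger/TE are flagged (warning + neutral
  value or rejection) rather than producing silent nonsense.
- Seeds: every stochastic component (signals, connectivity, permutations,
  bootstrap, searches) draws from explicit seeds; a search derives
  per-iteration streams from its master seed via `SeedSequence`, and rerun
  results are bit-identical.

## Known limitations

- No conductance driving forces, no multi-compartment or Hodgkin–Huxley
  dynamics, no plasticity during simulation.
- Transfer entropy is limited to one optimally shifted time point
  (k = l = 1); Granger causality is bivariate and linear; no spectral or
  conditional variants.
- The global-sum feedforward normalization makes the input gain
  seed-dependent (severalfold rate spread across connectivity draws); the
  inhibitory relay compresses but does not remove it.
- The 40× decimation is deliberately unfiltered, so high-frequency power
  aliases into the downsampled sequences exactly as in the documented
  procedure.
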