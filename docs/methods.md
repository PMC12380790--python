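# Methods

## Model summary

The simulator implements a six-population thalamo-cortical spiking network:
supragranular (S), middle (M) and deep (D) excitatory cortical layers,
shared cortical interneurons (CI), thalamo-cortical relay (TCR) and
thalamic reticular nucleus (TRN), with default sizes 100/100/100/100/100/40
(540 neurons). Neurons follow the quadratic Izhikevich model with a
discontinuous reset at a noisy peak threshold; synapses follow
Tsodyks–Markram (TM) short-term plasticity with facilitating, depressing
and pseudo-linear classes; stimulation is an intracellular rectangular
pulse train injected into every neuron of layer D. Units are mV and ms;
currents are on the Izhikevich dimensionless scale.

## Numerical scheme

* **Drift**: explicit Euler, default dt = 0.1 ms. The quadratic membrane
  term can diverge under explicit Euler at large steps, so validation warns
  for dt > 0.5 ms.
* **Membrane noise** ξ: added to v once per step. Two conventions are
  provided. `sqrt_dt` (default) adds σ·√dt·N(0,1), the Euler–Maruyama form
  whose ensemble variance grows as σ²t regardless of dt (verified against
  the analytic Wiener growth in the tests). `per_step` adds N(0,σ) directly
  — the convention of earlier implementations of this model family, in
  which the noise term is deliberately *not* multiplied by the time step;
  its effective strength then depends on dt. The two coincide at dt = 1 ms.
* **Threshold noise** ζ: drawn independently per neuron per step and added
  to the comparison threshold (v ≥ v_peak + ζ), exactly as the reset rule
  is written. The spike-step voltage is clamped to v_peak in recordings,
  the standard Izhikevich practice.
* **TM decay**: exact exponential maps per step for u, x and the PSC
  (unconditionally stable and analytically testable), rather than Euler
  decay. Spike jumps use the standard ordering: u jumps first, the
  released current uses post-jump u and pre-jump x, then x is depleted.
* **Intra-step order**: delayed-PSC read → aggregation → bias/background/
  DBS → neuron step → TM decay → TM spike update → buffer push → record.
  The continuous equations impose no order at discrete resolution; this
  order is fixed, documented, and pinned by the loop-oracle tests.
* **Blow-up guard**: state finiteness is checked every 500 steps; failure
  raises an error naming the step and structure.

## State granularity and delays

TM state is kept per (synapse class, presynaptic neuron) — 3×N vectors —
and the per-projection class mixture and weight are applied at aggregation.
The conduction delay Δ of a projection is applied when its PSC is read
back from a circular buffer rather than when the spike reaches the
synapse; since the PSC is a function of the presynaptic train alone, the
two formulations are equivalent, and the vectorized engine is verified
step-for-step against a naive reference (`tcmsim.reference`) that keeps
one TM state per individual synapse pair and applies delays on the spike
side. A projection with Δ = 0 acts with a one-step latency (the default
configuration uses 1 ms within cortex and within thalamus, 8 ms between
them). Delays are rounded to integer steps, with a warning when the
rounding error exceeds 10% of dt.

## Connectivity

All-to-all between every ordered structure pair with non-zero gain:
individual weights are gain(src→dst)/N_src × (1 + jitter·η), η ~ U(−1,1),
jitter 0.2 by default. Division by the presynaptic count keeps total input
invariant under population resizing; neuron self-loops are excluded;
weights inherit the sign of the source (excitatory ≥ 0, inhibitory ≤ 0).
The sign of each connection is carried once, by the weight; the TM
parameter A is used as a magnitude inside the engine so inhibitory
projections are not double-negated.

Randomness is split into named substreams (weights, heterogeneity,
membrane, threshold, background) derived from the master seed, so enabling
or disabling one noise source never shifts another's draws; two draws per
step are consumed for membrane and threshold noise even when their σ is 0.

## Default parameters and what they stand for

The population sizes, the noise levels (membrane σ 0.5, threshold σ 0.1),
the neglected Poissonian background, and the protocol (12 s, DBS onset at
6 s, target layer D) are fixed study conditions. The remaining numbers are
not printed anywhere authoritative for this model and ship as documented,
overridable stand-ins:

* **Neuron archetypes**: canonical Izhikevich parameter sets — RS
  (a=0.02, b=0.2, c=−65, d=8) for S/M/D/TCR, FS (a=0.1, b=0.2, c=−65, d=2)
  for CI, LTS (a=0.02, b=0.25, c=−65, d=2) for TRN; v_peak = 30 mV.
  Heterogeneity follows the standard Izhikevich randomization (excitatory:
  c, d perturbed ∝ r²; inhibitory: a, b ∝ r), scaled by a per-archetype
  `heterogeneity_scale` (default 1).
* **Synapse classes**: canonical cortical TM triplets — facilitating
  U=0.09/τ_f=138/τ_d=670, depressing U=0.5/17/671, pseudo-linear
  U=0.29/33/330; PSC decay τ_s = 3 ms (excitatory) / 11 ms (inhibitory).
  Excitatory projections default to a depression-dominated mixture
  (0.1/0.8/0.1), inhibitory ones to 0.1/0.3/0.6.
* **Bias currents**: 3.5 for the RS/FS populations and 0.8 for TRN —
  below each archetype's rheobase (so the isolated, noise-free network is
  silent) but close enough that the configured membrane noise sustains
  irregular firing at roughly 10–16 Hz per neuron.
* **Gains and the hub layout**: connection gains were calibrated, once, so
  that the unstimulated network expresses the two target phenomena — a
  synchronized beta-band population rhythm (spectral peak ≈ 14.5 Hz,
  coherence χ ≈ 0.85–0.98 per structure) and its frequency-dependent
  response to stimulation. Layer D is the hub: the
  D↔TCR loop (8 ms each way) and strong D→S/M projections distribute the
  rhythm, CI provides the shared inhibition that paces it, and S/M
  interconnections are deliberately weak. This layout makes cortical
  synchrony depend on D's *output synapses*, which is exactly what
  high-frequency stimulation suppresses.
* **DBS pulse**: monophasic rectangular, width 0.3 ms, amplitude 100
  (charge-balanced biphasic mode available). The amplitude is a tuning
  constant chosen so a pulse reliably discharges a resting D neuron
  (Δv ≈ amplitude × width = 30 mV) while 130 Hz drive still outruns the RS
  adaptation, scattering which pulses each neuron follows.

## Synchrony and spectral metrics

The rasters are quantified with two standard statistics. Population
synchrony uses the Golomb–Hansel coherence χ = √(Var_t[mean_i s_i] /
mean_i Var_t[s_i]) over per-neuron spike signals binned at 1 ms and
smoothed with a 5 ms Gaussian; χ is scale-invariant, 1 for identical
signals, and falls toward a finite-size floor (≈0.1–0.2 for 100
independent trains) for asynchronous activity. A population without any
temporal variance is assigned χ = 0. Spectra use a Welch averaged
periodogram (2 s Hann windows, 50% overlap) of the mean-subtracted
population activity; beta power integrates 13–30 Hz, total power 1 Hz to
Nyquist. Epochs default to seconds [1, 6) (pre-DBS) and [7, 12) (DBS),
excluding 1 s of settle-in after run start and after stimulation onset.
"Cortical" summaries average S, M, D and CI.

## What the simulations show — and what they do not

Under the default configuration, five paired seeds of the 12 s protocol
give mean cortical χ ≈ 0.89 pre-DBS, ≈ 0.90 during 20 Hz DBS and ≈ 0.75
during 130 Hz DBS, with cortical beta power falling to ≈ 65% of baseline
at 130 Hz and rising slightly at 20 Hz; these numbers are recomputed by
`scripts/acceptance.py` and asserted by the acceptance tests. They
demonstrate the *mechanism* — depression-mediated decoupling of the
stimulated hub — inside a calibrated model. They are not quantitative
predictions for any animal or patient: the gains and delays are stand-ins,
the model has no spatial geometry, no extracellular field or antidromic
activation, no long-term plasticity, and the "LFP" is a spike-count proxy,
not a field potential.

## Problem sizes used in the test suite

The oracle-equivalence checks run a 3-population × 10-neuron network for
10⁴ steps against the per-pair reference implementation; the headline
contrast runs the full 540-neuron, 12 s protocol for five paired seeds;
dt-robustness and CLI checks use shortened (2–5 s) or miniaturized
configurations. These sizes are the package's own validation choices and
are stated here so results are reproducible as printed.
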