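# Methods

`ramanline` is a software digital twin of an automated at-line Raman
measurement station for high-throughput fermentation monitoring: an
eight-well sampling interface feeding a flow-through cuvette via microfluidic
tubing, a multiplexer valve and a peristaltic pump, with a CNN predicting
glucose and acetate concentrations from each spectrum. Everything physical is
replaced by explicit, testable models; this note records those models, their
parameters and the design decisions behind them.

## Spectral forward model

A spectrum is

```
I(wn) = m · g · s · Σ_a c_a Σ_p A_p φ_p(wn) + B(wn) + ε(wn)
```

with analyte concentrations `c_a` (g/L), peak heights `A_p` (intensity per
g/L), line shapes `φ_p` (pseudo-Voigt with η = 0.5 by default; Gaussian and
Lorentzian selectable — pseudo-Voigt is standard Raman practice and keeps
closed-form band areas testable), optical gain `g`, cuvette-holder mirror
factor `m` (default 2: the retro-reflector doubles the collected signal) and
a signal scale `s ∈ [0, 1]` used by the rig when part of the optical window
holds air. The background `B` has two parts: an instrument-specific cubic
polynomial on the instrument's own normalised axis, and a sample-side
fluorescence term `F · exp(−d · u)` on the absolute wavenumber scale, scaled
by `m · g` because fluorescence is collected through the same optics as the
Raman signal. Attributing fluorescence to the sample rather than the
instrument is what lets per-spectrum normalisation align spectra across
instruments (see Harmonisation).

Peak positions are shipped, editable configuration at literature-typical
values; the one position treated as fixed is the 980 cm⁻¹ sulfate band of
MgSO₄, which doubles as the cleaning-verification marker. The glucose
cluster (1065, 1125, 1365, 1460 cm⁻¹) lies inside the 1000–1500 cm⁻¹
calibration band so that the calibration metric is sensitive to it. The
default grid is 2048 points over 65–3350 cm⁻¹.

Noise is additive i.i.d. Gaussian per point (optional signal-proportional
term available), with `noise_sd = 0.5` intensity units by default. The value
is anchored on the fermentation-scale task the instrument is used for: a
1 g/L acetate band rises ≈ 2.4 units above the background, so the per-point
SNR is ≈ 5, which places an ordinary linear least-squares reading of the
spectra at 1–3 % of the fermentation concentration ranges — the error regime
the modelled hardware demonstrably operates in. A substantially larger noise
would make the emulated task categorically harder than the system being
emulated; a smaller one would make the benchmark trivial.

The multi-instrument fleet generator varies grid (1650–2500 points,
shifted ranges), gain (0.6–1.5), mirror (1 or 2), baseline polynomial
(±40 %) and noise (0.3–0.9) across instruments, emulating the heterogeneous
pool of spectrometers behind the auxiliary training corpus.

## Fermentation trajectories

Batch phase (≈ 4 h): Monod growth (`μ_max = 0.7 h⁻¹`, `K_s = 0.05 g/L`,
`Y_xs = 0.45`) consumes glucose from 5 g/L to depletion while acetate
accumulates as an overflow product (0.25 g acetate per g glucose). Feeding
phase (≈ 4 h): glucose is held near a 0.1 g/L residual set-point and acetate
is slowly re-consumed. Ethanol starts at 2 g/L (needle-disinfectant
carry-over) and decays exponentially; MgSO₄ declines slowly from 2 g/L.
Initial values are jittered log-normally (σ = 0.1) across runs. The
integrator is plain forward Euler at 0.01 h. These dynamics exist to span
realistic concentration ranges with realistic temporal correlation — they
are not a validated process model, and nothing downstream depends on their
exact form.

## Fluidic path

Each channel is one dimensional: a volume coordinate (µL) from the well
outlet to the pump, holding an ordered list of labelled segments (sample
with per-analyte g/L, wash, air). Plug flow in 0.508 mm tubing justifies the
1-D picture. Default geometry: well capacity 125 µL, dead volume 5 µL,
well-to-valve tube 25.34 µL (125 mm × 0.508 mm ID), valve dead volume 40 µL,
valve-to-cuvette tube 13.17 µL (65 mm), connector 12.5 µL, cuvette 18 µL
with the optical window at 4–14 µL inside it, downstream (cuvette-to-pump)
150 µL. The valve and connector dead volumes are not published for the
hardware; they are configuration with these stated defaults.

Pumping shifts the segment column. Forward draws from the well — air once
the well is down to its dead volume — and expels the pump end to waste;
reverse draws wash from the reservoir and expels the well end into the well.
The well is bottom-fed and overflows at the top, so reverse inflow displaces
the *oldest* well content into the overflow: a long wash flush leaves the
well holding pure wash. Volume is conserved through every action (checked as
a property test over random 100-action sequences).

**Pull-back.** The step that empties a well after cleaning pumps forward by
V_pb, but only a fraction (default 0.3) of that flow is drawn from the well
— the remainder short-circuits through the overflow tee — and the well
cannot be pumped below its dead volume. Residual wash after pull-back is
therefore `max(dead, capacity − 0.3 · V_pb)`: strictly decreasing over the
350–400 µL grid and first reaching the 5 µL dead-volume floor at 400 µL.
This is the mechanism that gives the pull-back axis of the calibration
surface its slope; the true drain physics of the hardware are unknown, and
this rule is the simplest one that reproduces the qualitative behaviour
(larger pull-back ⇒ less residual dilution, eventually an air gap).

**Carry-over dispersion.** After pumping a volume V, every liquid/liquid
boundary can be replaced by a mixing zone of width `κ·√V` graded linearly in
six sub-segments, taken symmetrically from both sides so that every
analyte's mass is conserved exactly. The default is κ = 0 (pure plug flow):
carry-over in the hardware is argued to be systematic and small, so it is a
controlled knob rather than an always-on effect. Air boundaries do not mix.

**Timing.** The four mechanical steps carry fixed measured durations (valve
1.3 s, transport to cuvette 3.6 s, cleaning 10 s, pull-back 4.74 s) plus
0.56 s of software time; only spectrum acquisition is timed by volume/rate.
Overhead is their sum, 20.2 s, and a sample with N spectra of exposure τ
takes `20.2 + N·τ` seconds — 40.2 s at the default N = 2, τ = 10 s.
Re-selecting an already selected channel still costs the valve time: the
simplest contract consistent with per-step accounting. Cleaning immediately
after each channel needs K valve switches per cycle; deferring all cleaning
needs 2K, so the implemented strategy saves exactly one switch (1.3 s) per
channel.

## Measurement cycle

Per channel: switch valve → pump V_sc forward → acquire N spectra while
circulating V_m = 20 µL at rate `V_m/(N·τ)` (the plug advances V_m in total
across all N exposures, keeping it moving until the last one ends) →
predict and persist → reverse-clean with V_clean = 1250 µL → pull back V_pb.
An unpipetted well triggers a warning, not an error, and records
air-dominated spectra — the rig can run dry diagnostics. Prediction cost is
charged to the software-time constant.

Default parameters: V_sc = 115 µL, V_pb = 400 µL, V_m = 20 µL,
V_clean = 1250 µL, V_sample = 50 µL (≥ cuvette 18 + V_m 20, the fill rule),
N = 2, τ = 10 s. V_sc/V_pb defaults are this geometry's own calibrated
optimum region — the physical instrument's optimum depends on its geometry
and is not a target.

## Calibration

The metric is the arithmetic mean intensity over a fixed closed wavenumber
band on the native grid (no interpolation): glucose 80 g/L over
1000–1500 cm⁻¹, MgSO₄ 50 g/L over 960–1000 cm⁻¹. A ratiometric
signal-to-noise criterion is deliberately not used: a plain average is
robust to sample-placement variation and air bubbles. The grid spans
V_sc 75–140 µL × V_pb 350–400 µL in 5 µL steps (14 × 11 cells), three
replicate rounds executed round-major (every cell once, then the whole grid
again) so slow drifts decorrelate from cell order. Each cell conditions a
fresh channel (clean + pull-back at the cell's V_pb), pipettes the
calibration sample, and runs a full measurement cycle.

Optimum selection maximises the primary substance's cell mean; cells whose
across-round standard deviation exceeds 3× the grid median (configurable)
are rejected as outlier-driven; candidates within one pooled standard
deviation of the maximum are near-ties resolved by best mean-rank across
substances, then lexicographically. The 3× default is a choice — no
quantitative rejection threshold is published for the hardware.

The *reference scenario* used for recovery experiments sets κ = 4.0: under
pure plug flow the noise-free surface has an exact plateau of tied cells
along V_sc (the 50 µL plug covers the 10 µL window over a whole range of
transport volumes), so "the true optimum" would be ill-defined. κ = 4 erodes
the plug edges enough that the surface has a unique interior peak —
(125, 400) µL on the default geometry — while preserving unimodality in
V_sc and monotonicity in V_pb. Monotonicity in V_pb holds up to the optimal
V_sc; beyond it the smaller, less-diluted plug overshoots the window and the
trend legitimately reverses, so the property is asserted in the
sample-limited regime only.

## Harmonisation and augmentation

Spectra from different instruments are (1) linearly interpolated onto a
common grid (out-of-range policy: clip-to-edge by default, zero-fill
selectable) and (2) SNV-normalised per spectrum: `(x − mean)/max(std, ε)`
with population std and ε = 1e-8 guarding constants. No baseline correction
or smoothing is applied — the network is expected to learn its own encoding.
Noise-free spectra of identical samples on different fleet instruments
correlate > 0.99 after these two steps.

SNV removes absolute intensity scale, so per-spectrum normalised data only
retain concentration information relative to internal references (water
bands, fluorescence background). The synthetic spectra always contain those
references; a toy problem without them is information-deficient no matter
the model, which the test suite documents explicitly.

Training-time augmentation: MixUp (convex combinations of spectrum pairs
and their labels, λ ~ Beta(α, α), α = 0.2, paired within-batch by random
permutation) plus baseline-offset and slope-tilt jitter applied to the
normalised spectra (offset ±0.3 SNV units, slope ±2·10⁻⁴ SNV units per
cm⁻¹, applied with probability 0.5 per batch). Labels are untouched by the
shape jitter.

## The network

Input `(B, 1, D)` → pointwise stem to 16 channels with an ELU → 8 blocks →
global average pooling → affine map to the 2 targets. Each block:

```
out = skip(x) + α · PW(ELU(BN(DW(x))))
```

`DW` is a depthwise convolution (kernel 7, stride 2), `BN` per-channel batch
normalisation, `PW` a pointwise channel-mixing convolution, and α a
learnable scalar initialised to 0, so at initialisation every block is an
identity (up to pooling). The skip path is parameter-free: average pooling
by 2, channels duplicated when the width doubles. Channels double every two
blocks, capped at 128 (16, 32, 32, 64, 64, 128, 128, 128); eight stride-2
blocks take 2048 points to length 8 before pooling. Forward and backward
passes are hand-written NumPy (float32 by default), verified against
central-difference numeric gradients in float64.

Three choices matter for trainability and are worth recording. First, SNV
makes every spectrum zero-mean, so any *linear* stem pools to exactly zero
and a gated network would emit a constant at initialisation with gradient
reaching only the gate scalars; the ELU after the stem makes pooled features
sample-dependent from the first step. Second, batch normalisation inside the
conv branch — the usual companion of depthwise-separable stacks — keeps
branch activations well-scaled through depth; without it, opening the gates
relies on a noise-driven random walk of the 8 scalars and converges only for
lucky seeds. Third, the gate scalars form their own optimiser group with a
10× learning-rate multiplier, so the gates open within a few epochs and the
branches then train under a real error signal.

Training minimises MSE on z-scored targets (z-scoring stabilises the
two-analyte loss; predictions are de-standardised to g/L for reporting) with
AdamW — decoupled weight decay applied to weight matrices only — under a
linear warm-up (default 20 epochs in the general config) followed by
exponential decay `γ^epoch`. When a validation set is supplied, the
parameters from the best-validation epoch are restored at the end (the
validation curve of a small, heavily augmented run is not monotone). All
randomness flows through seeded generators; two runs with the same seed are
bit-identical.

Hyperparameter search is successive halving with reduction factor η = 3
(9 configurations, budgets 3/6/12 epochs in the benchmark): survivors are
the best 1/η by validation loss at each rung. Proposals are model-based — a
random-forest surrogate over completed trials ranks random candidates — with
a random fallback while the history holds fewer than 10 trials.

## The benchmark

The default synthetic benchmark mirrors the evaluation protocol of the
modelled system: 24 simulated fermentation experiments (9 samples each, 2
replicate spectra per sample, one primary instrument) split 8/8/8 by
experiment into train/validation/test — split hygiene is asserted on every
build — plus an auxiliary multi-instrument mixture corpus (600 spectra over
8 instruments, random mixtures over 0–10 g/L glucose, 0–2 g/L acetate,
0–3 g/L ethanol and MgSO₄) folded into training only. Harmonisation targets
a 1024-point grid and the final model trains for 100 epochs at batch 32
(peak LR 10⁻², γ = 0.98) after the Hyperband ladder; these problem sizes are
the package's own benchmark defaults, chosen to keep the full tune + train +
evaluate loop tractable on a single CPU while preserving every structural
element (multi-instrument harmonisation, experiment-wise splitting, tuning,
held-out evaluation). Test MAE is reported per analyte in g/L with one
prediction per sample (mean over its replicate spectra).

What passing the benchmark does and does not show: the synthetic task is
linear by construction with Gaussian noise and a perfectly known peak
library, so it validates the *pipeline* — harmonisation, augmentation,
optimisation, tuning, split hygiene, evaluation — not chemometric
performance on real fermentation broth, which adds matrix effects,
instrument drift, cosmic-ray spikes and model mismatch that the generator
deliberately omits (no biomass scattering either: the modelled system
measures cell-free supernatant).

## Store and provenance

The experiment store is a directory of JSONL tables plus per-spectrum CSV
arrays: validate-before-write, id-stamped, append-only, with an event log.
Its API (experiment management, spectra storage/export, sample annotation,
prediction and model persistence) is an interface a relational backend could
implement instead. Every CLI run writes a manifest with seed, configuration
hash and package version sufficient to re-run it.

## Known limitations

- No pressure/compliance, pulsation, temperature or bubble dynamics; the
  move-volume circulation exists only as a volume displacement.
- The pull-back drain rule is phenomenological; only its monotone shape, not
  its functional form, is grounded.
- Dispersion uses a single √V mixing-zone law per boundary; successive pumps
  compound zones approximately rather than by exact convolution.
- The fermentation model is intentionally minimal (no oxygen limitation, no
  biomass feedback on sampling).
- Raman cross-sections are not physically calibrated; peak heights are
  plausible, not measured.
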