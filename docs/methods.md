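# Methods

This note documents the models and procedures implemented in `alternans`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## 1. The CRU-lattice myocyte model (`alternans.crusim`)

### Model structure

The simulator represents a ventricular myocyte as a 3D lattice of Ca²⁺
release units (CRUs). Each CRU couples four Ca²⁺ pools:

* a cytosolic sub-volume with free Ca²⁺ `c` (µM),
* troponin-bound Ca²⁺ `b` with explicit kinetics
  `J_trpn = k_on (B_t − b) c − k_off b`,
  `k_on = 0.0327 (µM·ms)⁻¹`, `k_off = 0.5 ms⁻¹` (control) or
  `0.1 ms⁻¹` (slowed-unbinding variant), `B_t = 70 µM`,
* a network-SR (NSR) compartment refilled by SERCA uptake
  `v_max c^h/(c^h + K_D^h)` with `K_D = 0.25 µM`, `h = 2`,
* a junctional-SR (jSR) compartment that equilibrates with the NSR
  (first-order, `τ_refill`) and empties into the cytosol during a spark.

Spark dynamics implement the "3R" ingredients: **randomness** — per-step
Bernoulli ignition from a counter-based per-CRU random stream;
**recruitment** — the ignition rate grows as `c^γ` in local cytosolic Ca²⁺
(γ = 6) and as a steep power of jSR load, and neighbouring CRUs exchange
cytosolic and NSR Ca²⁺ diffusively (no-flux boundaries), so firing CRUs
promote their neighbours; **refractoriness** — a spark terminates when its
jSR falls below a fixed fraction of the reference load, after which the
CRU is absolutely refractory for `refractory_tau` and then remains
functionally refractory until its jSR reloads through the steep ignition
gate. Pacing applies a 2-ms trigger (flux plus ignition-rate boost, the
L-type-channel surrogate) to every dyad each cycle. Everything above is an independent
minimal construction in the established CRU-network tradition, calibrated
to the qualitative behaviour described below rather than transcribed from
any published model's equations.

### Troponin, buffering, and mass conservation

Troponin is the only buffer with resolved kinetics because its unbinding
rate is the scientific subject. All faster buffers (a lumped non-troponin
cytosolic pool, `B_f = 3 µM, K = 0.6 µM` — troponin is deliberately the
dominant cytosolic buffer, as it is in myocytes; calsequestrin in the
jSR, `400 µM, K = 600 µM`) use the rapid-buffering equilibrium — but rather
than dividing fluxes by the usual β(c) factor, the state carries *total*
(free + rapid-bound) Ca²⁺ per compartment and recovers free Ca²⁺ from the
binding quadratic at every step. This makes every update an exact pairwise
transfer, so in closed-cell mode (sarcolemmal fluxes off) total Ca²⁺ is
conserved to floating-point roundoff rather than to an O(dt²) integration
error; the conservation check is a real test of the flux bookkeeping, not
of an integrator tolerance.

`B_t = 70 µM` is the standard total troponin-site concentration in the
model family the k_on value comes from; it is called out here because
peak and diastolic Ca²⁺ both scale with it.

### Why slowed unbinding promotes alternans in this model

With `k_off = 0.1 ms⁻¹` the troponin equilibrium constant drops from
15.3 µM to 3.1 µM: troponin soaks up several extra µM of each release and
returns it late in the beat at low free Ca²⁺, where SERCA works far below
capacity. Cytosolic clearance therefore finishes later, diastolic Ca²⁺
stays elevated at short cycle lengths, and the SR is still refilling when
the next stimulus arrives. Release is steeply load-dependent (the
ignition gate), so an under-recovered beat releases much less, the SR
over-recovers, and the next beat is large: a period-2 (alternans)
rhythm. The control cell clears faster and stays period-1 on the whole
300–700-ms grid. The variant also keeps a higher diastolic free Ca²⁺ and
a lower diastolic SR load than control at matched cycle length, which is
the directional signature the model is asked to reproduce.

### Calibration

The physiology-fixed constants are k_on, the two k_off values, the SERCA
K_D and the lattice geometry. The remaining rates (ignition, release
conductance, refill and refractory times, pump v_max, sarcolemmal
exchange) were calibrated *once*, on the 20×5×5 test lattice, against two
qualitative endpoints: (a) the control variant paces 1:1 with no
alternans flag anywhere on the 300–700-ms PCL grid, and (b) the
reduced-k_off variant shows sustained alternans for every PCL below
500 ms and none at or above it (flag threshold 5%, majority over 5
seeds). Three structural choices make this separation possible and are
worth knowing when re-tuning:

* the NSR is shallow (1.5% of cytosolic volume), so jSR refill is
  rate-limited by SERCA reclaiming the released Ca²⁺ from the cytosol —
  SR recovery inherits the cytosolic clearance speed;
* the non-troponin fast buffer is small (3 µM), so troponin dominates
  cytosolic buffering (as it does in real myocytes) and the two k_off
  variants differ maximally in clearance speed;
* ignition is gated by (j/400 µM)^16, so a fully reloaded lattice sits on
  the saturated (quiet) branch of the trigger curve and only genuine
  under-recovery reaches the steep flank.

Calibrated values (frozen in `make_default_params` and the dataclass
defaults): SERCA v_max = 0.024 µM/ms; release conductance 2×10⁻³ ms⁻¹;
ignition 0.3·c⁶ ms⁻¹; trigger boost 8 ms⁻¹ (2 ms); refractory 80 ms;
jSR↔NSR τ = 15 ms; spark termination at 0.35 of the 400-µM gate
reference; NCX scale 0.008 ms⁻¹; background influx 8×10⁻⁴ µM/ms;
diffusive coupling 0.6/0.1 ms⁻¹ (cytosol/SR). The full 100×20×10
(20,000-CRU) lattice runs with the same per-CRU parameters.

### Numerics

Explicit Euler with `dt = 0.05 ms` (admissible range (0, 0.1]); the
fastest deterministic time constants (troponin binding ≈ 2 ms, spark
drain ≈ 5–10 ms) are comfortably resolved, and halving dt changes
deterministic per-beat peaks by <1% (tested). Stochastic ignition draws
come from a splitmix64-style hash of (seed, CRU index, step), i.e. one
counter-based stream per CRU: trajectories are bit-reproducible for a
given seed and the stream of CRU *i* does not depend on the lattice size.
State fields are clamped non-negative only through flux limiting; a
non-finite field aborts the run with the offending field and time.
Whole-cell traces are recorded at 1-ms resolution.

Voltage is a prescribed action-potential waveform by default
(`clamped_waveform`) so the Ca²⁺ analysis does not depend on an AP model;
an optional `coupled_minimal_ap` mode drives a phenomenological membrane
ODE with a Ca²⁺-dependent inward current so voltage alternans can appear
secondary to Ca²⁺ alternans. All calibrated results use the default mode.

## 2. In-vitro kinetics (`alternans.kinetics`)

Steady-state titrations are fitted per technical replicate with
`F(Ca) = f_min + (f_max − f_min)·Ca^n/(K_d^n + Ca^n)`; the construct's
K_d is the across-replicate mean ± SEM (per-replicate-then-aggregate, not
a pooled fit). The Hill coefficient is free by default — cooperative
thin-filament binding is expected but its value is not prescribed — with
`fix_hill_n` available. Initial values are analytically seeded (K_d from
the half-span crossing, multistart over n ∈ {0.5, 1, 2, 4}), making the
fit robust without manual tuning.

Stopped-flow decays are fitted with `F(t) = A·exp(−kt) + C` on
`t ≥ dead time` (1.1 ms by default — the pre-dead-time segment does not
exist in the data). `k` is reported in s⁻¹, the standard unit for
stopped-flow dissociation at 15 °C. Traces can be averaged first
(`average_traces`, warning below five traces) or fitted individually and
aggregated as mean ± SEM.

Two-construct comparisons use the unpaired pooled-variance Student t
test, two-sided, α = 0.05. (The transcriptomics module deliberately uses
Welch instead — the two modules follow the two different tests named for
their respective data.)

## 3. Transient-trace analysis (`alternans.traces`)

Beats are stimulus-aligned half-open windows `[s_i, s_{i+1})`; a beat is
kept when its peak exceeds the pre-stimulus baseline by 4 baseline-noise
SDs plus a √(2 ln n) window-maximum correction (the expected maximum of n
noise samples), so skipped beats are not resurrected by noise. The
baseline is the median of the three pre-stimulus samples because at 100
frames/s an optical upstroke is sub-frame and the first in-window sample
may already sit on it. Activation time is the maximum first difference
after the stimulus — more robust at 10 ms/frame than a threshold
crossing. Durations (APD₃₀/APD₈₀ for the voltage-like channel,
CaTD₃₀/CaTD₈₀ for the Ca²⁺-like channel) run from activation to the
first post-peak crossing of the recovery level, linearly interpolated
between samples; triangulation is `(APD₈₀ − APD₃₀)/APD₈₀`. The alternans
ratio is the absolute difference of even- and odd-beat mean peaks over
the grand mean (threshold 0.05); in the rhythm report the parity is taken
from the stimulus index so missed beats cannot scramble the phase.
Entrainment means every stimulus evoked exactly one well-formed
transient; irregular counts are missed stimuli plus transients that never
recover to the 80% level.

Frequency summaries report mean ± SEM per (group, rate), pairwise
unpaired Student t tests between groups at each rate, and one-way ANOVA
with Tukey HSD across rates within a group.

## 4. Synthetic data (`alternans.synth`)

Each generator reproduces the statistical structure one stage consumes,
is bit-deterministic given its seed, and attaches its ground truth for
recovery tests. The assay noise magnitudes are not published anywhere;
the defaults below are implementer-chosen, configurable, and state what
passing tests show: the *pipeline* recovers what it is pointed at, not
that any instrument behaves this way.

* **Titrations** — Hill curves on a 17-point log grid (0.01–100 µM),
  Gaussian noise 2% of span, 8 replicates.
* **Stopped flow** — exponentials sampled every 0.05 ms from the 1.1-ms
  dead time, noise SD 2% of amplitude.
* **Transient trains** — each beat is a fast half-cosine upstroke (6 ms
  voltage-like, 10 ms Ca²⁺-like; max slope = the activation reference)
  followed by a monotone PCHIP repolarization pinned to the requested
  30%/80% recovery times — only duration metrics are constrained, the
  waveform between knots is free. Stimuli start after 0.5 s of baseline;
  `n = ⌊duration·rate/60⌋` stimuli are delivered and the record is padded
  so the last beat completes. Alternate beats scale by `1 ± ratio/2`;
  skipped indices produce no pulse. Polarity −1 models dyes whose
  fluorescence falls on depolarization.
* **Counts** — gamma-Poisson (negative-binomial-like), per-gene
  log-normal baselines around 500 counts, housekeeping genes abundant and
  unchanged by construction. The default injected program is a 68-gene
  remodeling-like signature (45 up, led by 18.6- and 5.9-fold
  natriuretic-peptide inductions, Notch and collagen transcripts at
  2–4.5-fold; 23 down at 0.3–0.6-fold) with extra-Poisson CV 10%
  (dispersion 0.01). The breadth matters statistically: with group sizes
  (4, 3) the Welch degrees of freedom can fall to ≈2, and the
  Benjamini–Yekutieli penalty `m·c(m) ≈ 1440` for 236 genes means an
  isolated true effect is frequently unrecoverable no matter how small
  the noise; a broad program fills the low ranks of the step-up and lets
  the headline genes through, which is also the situation the assay this
  emulates actually reported.

What the generators do **not** emulate: photobleaching, motion artifact
and optical point-spread in the trains; probe-specific hybridization
efficiency and cartridge effects in the counts; ionic-strength or
temperature dependence in the kinetics. Conclusions from passing tests
are therefore about the estimators, not about instrument physics.

## 5. Differential expression (`alternans.dge`)

Per-sample scale factors are the geometric mean of the seven
housekeeping-gene counts, anchored to the across-sample geometric mean;
counts are divided by the factor and transformed `log₂(x+1)`. The +1
pseudocount is the standard guard for zero counts, and it is why
per-sample rescaling cancels only up to O(1/count). Testing is per-gene Welch (unequal variance,
Welch–Satterthwaite df) on the log₂ values, two-sided;
Benjamini–Yekutieli step-up over all tested genes; a gene is
differentially expressed at adjusted p < 0.05 with no fold-change
cutoff. Fold orientation is variant-over-control (second group label over
first). An optional detection filter keeps genes whose mean count exceeds
mean + 2 SD of negative-control probes — a synthetic stand-in for a
proprietary background-threshold rule, and labelled as such.

ΔΔCt folds use the arithmetic mean of the two reference-gene Ct values
(equal to geometric-mean normalization in linear space), ΔΔCt between
group means, fold = 2^(−ΔΔCt).

## 6. Pipeline (`alternans.pipeline`)

Stage seeds are `crc32(master_seed ":" stage) & 0x7fffffff`, so adding a
stage never perturbs another stage's data. Every output file is recorded
in a manifest with its SHA-256; identical configs reproduce identical
manifests, which is the end-to-end determinism contract. A stage failure
halts its dependents and is recorded in the manifest rather than raised.

## 7. Problem sizes and tolerances used by the shipped checks

The simulation checks run on the 20×5×5 test lattice with 34 beats per
cycle length — 18 discarded as the approach to the attractor, 16 recorded
— on the 300–700-ms grid in 50-ms steps with majority voting over 5
seeds; the scale is chosen for a desk-class machine, and the 20,000-CRU
lattice is supported with the same per-CRU parameters. The alternans
flag compares even- and odd-beat mean peaks over the recorded window
(identical to the last-two-beat comparison when two beats are recorded);
averaging over 16 beats keeps the 500-CRU lattice's ~3% single-beat shot
noise clear of the 5% flag threshold at stable cycle lengths.
Kinetics recovery uses the replicate counts of the emulated experiments
(8/6 titrations, 9/11 stopped-flow traces). The null-FDR simulation uses
1,000 replicate 236-gene matrices at group sizes (4, 3). Fit tolerances:
noiseless recoveries to 1e-6 (relative); noisy ratio recoveries to
10% (Kd) and 5% (k_off); conservation drift below 1e-4 over 10 s;
troponin equilibrium to 1e-6 relative.

## 8. Known limitations

* The CRU model is a minimal mechanism-class model: no Ca²⁺ waves,
  no spatially discordant alternans, no full ionic action potential, no
  attempt to match any published model's fluxes quantitatively.
* Alternans classification at the 5% threshold on 500 CRUs operates a
  few multiples above the lattice shot noise; much smaller lattices will
  flicker.
* The Hill fitter assumes a monotone saturating titration; biphasic
  curves are out of scope.
* Welch + BY at (4, 3) has intrinsically low single-gene power (see §4);
  the package reports what the statistics support rather than working
  around it.
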