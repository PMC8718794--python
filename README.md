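# alternans

**Ca²⁺-handling analysis toolkit for a slow-unbinding cardiac troponin-T
variant.**

Hypertrophic-cardiomyopathy mutations in cardiac troponin T (such as the
I79N substitution) increase myofilament Ca²⁺ sensitivity by slowing Ca²⁺
dissociation from troponin C. Slowed unbinding keeps Ca²⁺ on the
myofilaments into diastole and, at fast pacing rates, promotes *Ca²⁺
alternans* — a period-2 beat-to-beat alternation of the Ca²⁺ transient
that is a recognized arrhythmia precursor. This package re-implements the
complete quantitative chain used to study that mechanism, from raw assay
data to the arrhythmia-relevant readouts, with a seeded synthetic-data
generator for every stage so the whole pipeline runs without any external
data:

| module | what it does |
| --- | --- |
| `alternans.crusim` | stochastic 3D lattice of ~500–20,000 coupled Ca²⁺ release units with explicit troponin buffering `J_trpn = k_on(B_t−[CaT])[Ca²⁺] − k_off[CaT]`; pacing protocols and bifurcation (peak-Ca vs pacing-cycle-length) scans |
| `alternans.kinetics` | Hill fits of steady-state Ca²⁺ titrations (K_d ± SEM per construct) and single-exponential fits of stopped-flow decays (k_off, 1.1-ms dead time); Student-t construct comparison |
| `alternans.traces` | optical-mapping transient metrics: APD₃₀/APD₈₀, CaTD₃₀/CaTD₈₀, triangulation (APD₈₀−APD₃₀)/APD₈₀, alternans ratio, entrainment classification |
| `alternans.dge` | housekeeping-normalized count statistics: per-gene Welch t, Benjamini–Yekutieli FDR, DEG calls, ΔΔCt fold changes |
| `alternans.synth` | seeded generators for titrations, stopped-flow decays, paced transient trains (100 frames/s) and gamma-Poisson count matrices |
| `alternans.pipeline` | deterministic multi-stage orchestration with hashed manifests |

The model at the core of `crusim` is a minimal "3R" lattice: sparks fire
**r**andomly with a rate that grows with local Ca²⁺ and junctional-SR
load, **r**ecruit their neighbours through diffusive coupling, and leave
each release unit **r**efractory until its junctional SR reloads. The
troponin off-rate is the only parameter that differs between the two
built-in variants (0.5 ms⁻¹ control vs 0.1 ms⁻¹ slowed), and the
alternans boundary that separates them is an emergent property of Ca²⁺
recycling, not a hard-coded switch. See `docs/methods.md` for the model,
its assumptions and the calibration.

## Worked example

`examples/01_hill_kd_fit.py` generates titrations for two constructs with
a true 1.7-fold K_d separation and recovers it:

```
WT       Kd = 3.460 +/- 0.028 uM (n = 8, Hill n = 1.52)
variant  Kd = 2.002 +/- 0.024 uM (n = 6, Hill n = 1.50)
Kd ratio WT/variant = 1.73  (p = 7.22e-14)
```

The ratio near 1.7 means the variant reaches half-maximal fluorescence at
a 1.7-fold lower Ca²⁺ concentration — it is Ca²⁺-sensitized — and the
unpaired t test on per-replicate K_d values confirms the separation is
far outside replicate noise.

`examples/04_alternans_bifurcation.py` paces both simulator variants at a
400-ms cycle length and prints the last recorded beat peaks and the
alternans flag; `examples/03_transient_metrics.py` and
`examples/05_differential_expression.py` walk the trace-metric and
DEG stages the same way. Each example is a short narrative script that
builds its own input, runs one capability and explains the numbers it
prints.

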