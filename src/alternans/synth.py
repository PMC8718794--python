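"""Seeded synthetic-data generators for every downstream analysis stage.

Each generator emulates the statistical structure of one assay:

* :func:`gen_titration` — Hill-shaped Ca2+ titrations with replicate noise;
* :func:`gen_stopped_flow` — single-exponential fluorescence decays
  truncated at the instrument dead time (1.1 ms by default);
* :func:`gen_transient_train` — paced dual-channel (voltage-like and
  Ca2+-like) transient trains at 100 frames/s with optional period-2
  alternans and skipped beats;
* :func:`gen_counts` — gamma-Poisson (negative-binomial-like) count
  matrices with stable housekeeping genes and injected fold changes.

All generators are deterministic given their seed and attach the
generating parameters as ``truth`` for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dge import DEFAULT_HOUSEKEEPING, CountMatrix
from .exceptions import InvalidParameterError
from .kinetics import StoppedFlowDataset, TitrationDataset, exp_decay_curve, hill_curve
from .traces import TransientTrace, bpm_to_pcl

__all__ = [
    "SynthSpec",
    "generate",
    "gen_titration",
    "gen_stopped_flow",
    "gen_transient_train",
    "gen_counts",
]

_KINDS = ("titration", "stopped_flow", "transient_train", "counts")


@dataclass
class SynthSpec:
    """Declarative description of one synthetic dataset."""

    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise InvalidParameterError("seed must be a non-negative integer")


def generate(spec: SynthSpec):
    """Dispatch a :class:`SynthSpec` to its generator."""
    fn = {
        "titration": gen_titration,
        "stopped_flow": gen_stopped_flow,
        "transient_train": gen_transient_train,
        "counts": gen_counts,
    }[spec.kind]
    return fn(seed=spec.seed, **spec.parameters)


def write_truth_json(obj, path) -> None:
    """Write a dataset's ground-truth sidecar as JSON."""
    Path(path).write_text(json.dumps(obj.truth, indent=1, default=str))


# ---------------------------------------------------------------------------


def gen_titration(
    true_kd: float,
    hill_n: float = 1.5,
    f_min: float = 10.0,
    f_max: float = 110.0,
    ca_grid: Sequence[float] | None = None,
    n_replicates: int = 8,
    noise_sd: float | None = None,
    seed: int = 0,
    construct_label: str = "",
) -> TitrationDataset:
    """Synthetic Ca2+ titration replicates around a Hill curve.

    ``noise_sd`` defaults to 2% of the fluorescence span. The Ca2+ grid
    defaults to 17 log-spaced points spanning 0.01-100 uM, bracketing any
    physiological Kd.
    """
    if true_kd <= 0:
        raise InvalidParameterError("true_kd must be > 0")
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if f_max <= f_min:
        raise InvalidParameterError("f_max must exceed f_min")
    if ca_grid is None:
        ca_grid = np.logspace(-2, 2, 17)
    ca_grid = np.asarray(ca_grid, dtype=float)
    if ca_grid.size == 0:
        raise InvalidParameterError("ca_grid must be non-empty")
    if (ca_grid <= 0).any() or not np.all(np.diff(ca_grid) > 0):
        raise InvalidParameterError("ca_grid must be strictly increasing and positive")
    if noise_sd is None:
        noise_sd = 0.02 * (f_max - f_min)
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    ideal = hill_curve(ca_grid, true_kd, hill_n, f_min, f_max)
    frames = []
    for rep in range(n_replicates):
        fluor = ideal + rng.normal(0.0, noise_sd, size=ca_grid.shape)
        frames.append(
            pd.DataFrame({"ca_uM": ca_grid, "fluor": fluor, "replicate": rep})
        )
    return TitrationDataset(
        points=pd.concat(frames, ignore_index=True),
        construct_label=construct_label,
        truth={
            "true_kd": true_kd,
            "hill_n": hill_n,
            "f_min": f_min,
            "f_max": f_max,
            "noise_sd": noise_sd,
            "n_replicates": n_replicates,
            "seed": seed,
        },
    )


def gen_stopped_flow(
    true_koff: float,
    amplitude: float = 1.0,
    offset: float = 0.1,
    t_end: float = 60.0,
    dt: float = 0.05,
    dead_time: float = 1.1,
    n_traces: int = 9,
    noise_sd: float = 0.02,
    seed: int = 0,
    construct_label: str = "",
) -> StoppedFlowDataset:
    """Synthetic stopped-flow decays, truncated at the instrument dead time.

    ``true_koff`` is in s^-1; times are in ms. Each trace is
    ``A*exp(-k t) + C`` plus Gaussian noise, sampled on
    ``[dead_time, t_end]`` — the earlier segment is unobservable, as in
    the real instrument.
    """
    if true_koff <= 0:
        raise InvalidParameterError("true_koff must be > 0")
    if dead_time < 0 or dt <= 0:
        raise InvalidParameterError("dead_time must be >= 0 and dt > 0")
    if t_end <= dead_time:
        raise InvalidParameterError("t_end must exceed dead_time")
    if n_traces < 1 or noise_sd < 0:
        raise InvalidParameterError("n_traces >= 1 and noise_sd >= 0 required")

    rng = np.random.default_rng(seed)
    k_per_ms = true_koff / 1000.0
    t = np.arange(dead_time, t_end + 0.5 * dt, dt)
    ideal = exp_decay_curve(t, amplitude, k_per_ms, offset)
    frames = []
    for tid in range(n_traces):
        fluor = ideal + rng.normal(0.0, noise_sd, size=t.shape)
        frames.append(pd.DataFrame({"t_ms": t, "fluor": fluor, "trace_id": tid}))
    return StoppedFlowDataset(
        traces=pd.concat(frames, ignore_index=True),
        dead_time=dead_time,
        construct_label=construct_label,
        truth={
            "true_koff": true_koff,
            "amplitude": amplitude,
            "offset": offset,
            "dead_time": dead_time,
            "noise_sd": noise_sd,
            "n_traces": n_traces,
            "seed": seed,
        },
    )


def _pulse_template(t_ms: np.ndarray, d30: float, d80: float, rise_ms: float) -> np.ndarray:
    """Unit-amplitude transient whose 30%/80% recovery times are d30/d80.

    A half-cosine upstroke (max slope at ``rise_ms/2``, the activation
    reference) is followed by a monotone PCHIP repolarization pinned to
    pass through the requested 30% and 80% recovery levels measured from
    activation. Only duration metrics are constrained; the waveform shape
    between the knots is a smooth monotone interpolant.
    """
    t_act = rise_ms / 2.0
    t_peak = rise_ms
    tail = d80 + 0.6 * (d80 - d30) + 20.0
    knots_t = np.array([t_peak, t_act + d30, t_act + d80, t_act + tail])
    knots_f = np.array([1.0, 0.70, 0.20, 0.0])
    decay = PchipInterpolator(knots_t, knots_f)
    out = np.zeros_like(t_ms)
    rising = (t_ms >= 0) & (t_ms < t_peak)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * t_ms[rising] / rise_ms))
    falling = (t_ms >= t_peak) & (t_ms <= t_act + tail)
    out[falling] = decay(t_ms[falling])
    return np.clip(out, 0.0, 1.0)


def gen_transient_train(
    rate: float = 55.0,
    duration: float = 20.0,
    frame_rate: float = 100.0,
    apd30: float = 210.0,
    apd80: float = 300.0,
    catd30: float = 250.0,
    catd80: float = 380.0,
    alternans_ratio: float = 0.0,
    skipped_beats: Sequence[int] = (),
    noise_sd: float = 0.0,
    polarity: int = +1,
    baseline_f0: float = 100.0,
    rel_amplitude: float = 0.5,
    onset_delay: float = 0.5,
    seed: int = 0,
) -> TransientTrace:
    """Paced dual-channel transient train with controllable beat metrics.

    After ``onset_delay`` seconds of quiet baseline, stimuli are placed
    every ``60/rate`` seconds, ``n = floor(duration * rate / 60)`` of them
    over the ``duration``-second pacing interval (the record itself is
    padded by ``onset_delay`` so the last beat completes); each evokes one
    pulse per channel
    whose 30%/80% recovery times match the requested durations (ms) at the
    sample-interpolation level. ``alternans_ratio`` scales alternate beats
    by ``1 +/- ratio/2``; indices in ``skipped_beats`` produce no transient
    (an irregular, non-entrained response). The raw signal is
    ``baseline_f0 * (1 + rel_amplitude * pulse)`` so that dF/F
    normalization applies; ``noise_sd`` is a fraction of the pulse
    amplitude. ``polarity=-1`` flips the voltage-like channel, emulating
    dyes whose fluorescence falls on depolarization.
    """
    if rate <= 0 or duration <= 0 or frame_rate <= 0:
        raise InvalidParameterError("rate, duration and frame_rate must be positive")
    pcl_ms = bpm_to_pcl(rate)
    for name, (d30, d80) in {"apd": (apd30, apd80), "catd": (catd30, catd80)}.items():
        if not (0 < d30 < d80):
            raise InvalidParameterError(f"need 0 < {name}30 < {name}80")
        if d80 >= pcl_ms:
            raise InvalidParameterError(
                f"{name}80 = {d80} ms must be shorter than the cycle length {pcl_ms} ms"
            )
    if not 0 <= alternans_ratio < 1:
        raise InvalidParameterError("alternans_ratio must be in [0, 1)")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if polarity not in (+1, -1):
        raise InvalidParameterError("polarity must be +1 or -1")

    if onset_delay <= 0:
        raise InvalidParameterError("onset_delay must be positive (baseline window)")
    rng = np.random.default_rng(seed)
    n_beats = int(np.floor(duration * rate / 60.0 + 1e-9))
    stim_s = onset_delay + np.arange(n_beats) * (pcl_ms / 1000.0)
    time = np.arange(0.0, duration + onset_delay, 1.0 / frame_rate)
    skipped = set(int(i) for i in skipped_beats)

    signals = {}
    for channel, (d30, d80), rise in (
        ("voltage", (apd30, apd80), 6.0),
        ("calcium", (catd30, catd80), 10.0),
    ):
        sig = np.zeros_like(time)
        for i, s in enumerate(stim_s):
            if i in skipped:
                continue
            scale = 1.0 + (alternans_ratio / 2.0) * (1 if i % 2 == 0 else -1)
            t_rel_ms = (time - s) * 1000.0
            sig += scale * _pulse_template(t_rel_ms, d30, d80, rise)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        sign = polarity if channel == "voltage" else +1
        signals[channel] = baseline_f0 * (1.0 + sign * rel_amplitude * sig)

    return TransientTrace(
        time=time,
        channels=signals,
        stimulus_times=stim_s,
        polarity={"voltage": polarity, "calcium": +1},
        truth={
            "rate_bpm": rate,
            "apd30": apd30,
            "apd80": apd80,
            "catd30": catd30,
            "catd80": catd80,
            "alternans_ratio": alternans_ratio,
            "skipped_beats": sorted(skipped),
            "noise_sd": noise_sd,
            "n_beats": n_beats,
            "seed": seed,
        },
    )


#: Default injected expression program: a hypertrophic-remodeling-like
#: signature with two strongly induced natriuretic-peptide genes (18.6- and
#: 5.9-fold), moderately upregulated Notch and collagen transcripts, and a
#: downregulated pluripotency/developmental block — 45 genes up and 23 down.
DEFAULT_FOLD_CHANGES: dict = {
    "NPPA": 18.6,
    "NPPB": 5.9,
    "NOTCH1": 2.8,
    "NOTCH3": 3.2,
    "NOTCH4": 2.5,
    "JAG1": 2.2,
    "HEY1": 2.6,
    "COL1A1": 4.5,
    "COL3A1": 3.8,
    "COL9A2": 3.0,
    **{f"UP{i:02d}": round(1.8 + 0.08 * i, 2) for i in range(1, 36)},
    "SOX2": 0.35,
    "BMP4": 0.45,
    **{f"DN{i:02d}": round(0.30 + 0.015 * i, 3) for i in range(1, 22)},
}


def gen_counts(
    n_genes: int = 236,
    group_sizes: tuple[int, int] = (4, 3),
    housekeeping: Sequence[str] | None = None,
    fold_changes: Mapping[str, float] | None = None,
    dispersion: float = 0.01,
    baseline_mean: float = 500.0,
    group_labels: tuple[str, str] = ("WT", "variant"),
    seed: int = 0,
) -> CountMatrix:
    """Gamma-Poisson count matrix with injected group-2 fold changes.

    Per-gene baseline means are log-normally scattered around
    ``baseline_mean``; counts are Poisson draws whose rates are gamma
    perturbed with the given ``dispersion`` (squared coefficient of
    variation of the extra-Poisson noise), the standard overdispersed
    count model. Housekeeping genes have fold 1 by construction; genes in
    ``fold_changes`` have their group-2 mean multiplied by the fold.
    Defaults mirror a two-genotype panel with 4 vs 3 samples and the
    remodeling-like program of :data:`DEFAULT_FOLD_CHANGES` (68 regulated
    genes, led by 18.6- and 5.9-fold inductions).
    """
    housekeeping = list(DEFAULT_HOUSEKEEPING if housekeeping is None else housekeeping)
    if fold_changes is None:
        # trim the default program (insertion order, strongest genes first)
        # to whatever fits beside the housekeeping set
        room = max(0, n_genes - len(housekeeping))
        fold_changes = dict(list(DEFAULT_FOLD_CHANGES.items())[:room])
    else:
        fold_changes = dict(fold_changes)
    if len(group_sizes) != 2 or min(group_sizes) < 2:
        raise InvalidParameterError("two groups of >= 2 samples are required")
    overlap = set(housekeeping) & set(fold_changes)
    if overlap:
        raise InvalidParameterError(
            f"housekeeping genes cannot carry fold changes: {sorted(overlap)}"
        )
    if any(f <= 0 for f in fold_changes.values()):
        raise InvalidParameterError("all fold changes must be > 0")
    if dispersion < 0 or baseline_mean <= 0:
        raise InvalidParameterError("dispersion >= 0 and baseline_mean > 0 required")

    named = housekeeping + [g for g in fold_changes if g not in housekeeping]
    if n_genes < len(named):
        raise InvalidParameterError(f"n_genes must be >= {len(named)} to hold named genes")
    genes = named + [f"GENE{i:04d}" for i in range(n_genes - len(named))]

    rng = np.random.default_rng(seed)
    base = baseline_mean * rng.lognormal(mean=0.0, sigma=0.8, size=n_genes)
    # housekeeping genes: abundant and (by construction) unchanged
    base[: len(housekeeping)] = baseline_mean * rng.uniform(2.0, 6.0, len(housekeeping))

    n1, n2 = group_sizes
    samples = [f"{group_labels[0]}_{i+1}" for i in range(n1)] + [
        f"{group_labels[1]}_{i+1}" for i in range(n2)
    ]
    groups = pd.Series([group_labels[0]] * n1 + [group_labels[1]] * n2, index=samples)
    fold_vec = np.ones(n_genes)
    for g, f in fold_changes.items():
        fold_vec[genes.index(g)] = f

    mean_matrix = np.tile(base[:, None], (1, n1 + n2))
    mean_matrix[:, n1:] *= fold_vec[:, None]
    if dispersion > 0:
        shape = 1.0 / dispersion
        rates = rng.gamma(shape, mean_matrix / shape)
    else:
        rates = mean_matrix
    counts = rng.poisson(rates).astype(float)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        groups=groups,
        housekeeping=housekeeping,
        truth={
            "fold_changes": fold_changes,
            "dispersion": dispersion,
            "baseline_mean": baseline_mean,
            "group_sizes": list(group_sizes),
            "seed": seed,
        },
    )
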