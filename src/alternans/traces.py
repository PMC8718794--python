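"""Per-beat metrics from optical-mapping style voltage/Ca2+ transient traces.

A :class:`TransientTrace` holds one or two fluorescence channels sampled on
a uniform grid (default 100 frames/s) together with the field-stimulation
times. The analysis mirrors what custom optical-mapping software computes:
dF/F normalization, stimulus-aligned beat segmentation, durations at a
chosen recovery fraction (APD30/APD80 for voltage, CaTD30/CaTD80 for Ca2+)
with linear sub-frame interpolation, the triangulation index
(APD80 - APD30)/APD80, an even/odd-beat alternans ratio, and an
entrainment report counting irregular (missed, extra or unrecovered)
transients against the stimulus train.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InvalidMetricError,
    InvalidParameterError,
    NormalizationError,
)

__all__ = [
    "TransientTrace",
    "Beat",
    "BeatMetrics",
    "RhythmReport",
    "ALTERNANS_THRESHOLD",
    "normalize_dff",
    "segment_beats",
    "duration_at_recovery",
    "triangulation_index",
    "alternans_metric",
    "entrainment_check",
    "beat_metrics_table",
    "pcl_to_bpm",
    "bpm_to_pcl",
    "summarize_by_frequency",
]

#: Relative even/odd peak separation above which beat-to-beat alternation
#: is flagged as alternans.
ALTERNANS_THRESHOLD = 0.05

#: A transient is "well formed" when its peak exceeds baseline by this many
#: baseline-noise standard deviations.
DETECTION_SIGMA = 4.0


@dataclass
class TransientTrace:
    """Uniformly sampled transient recording with stimulus annotations."""

    time: np.ndarray  # s
    channels: dict  # name -> np.ndarray, same length as time
    stimulus_times: np.ndarray  # s
    polarity: dict = field(default_factory=dict)  # name -> +1/-1
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise InvalidParameterError("time grid must be uniform and increasing")
        for name, sig in self.channels.items():
            self.channels[name] = np.asarray(sig, dtype=float)
            if len(self.channels[name]) != len(self.time):
                raise InvalidParameterError(f"channel {name!r} length mismatch")
        if len(self.stimulus_times) and (
            self.stimulus_times.min() < self.time[0] - 1e-9
            or self.stimulus_times.max() > self.time[-1] + 1e-9
        ):
            raise InvalidParameterError("stimulus times outside the record")
        for name in self.channels:
            self.polarity.setdefault(name, +1)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def to_csv(self, path, stim_path=None) -> None:
        """Write the trace as CSV plus a stimulus-times sidecar.

        ``stim_path`` defaults to ``<path stem>.stim.csv``; ground truth,
        when present, goes to ``<path stem>.truth.json``.
        """
        path = Path(path)
        cols = {"t_s": self.time}
        cols.update(self.channels)
        pd.DataFrame(cols).to_csv(path, index=False)
        stim_path = Path(stim_path) if stim_path else path.with_suffix(".stim.csv")
        pd.DataFrame({"stim_s": self.stimulus_times}).to_csv(stim_path, index=False)
        if self.truth:
            path.with_suffix(".truth.json").write_text(json.dumps(self.truth, indent=1))

    @classmethod
    def from_csv(cls, path, stim_path=None) -> "TransientTrace":
        path = Path(path)
        df = pd.read_csv(path)
        stim_path = Path(stim_path) if stim_path else path.with_suffix(".stim.csv")
        stim = pd.read_csv(stim_path)["stim_s"].to_numpy()
        channels = {c: df[c].to_numpy() for c in df.columns if c != "t_s"}
        return cls(time=df["t_s"].to_numpy(), channels=channels, stimulus_times=stim)


@dataclass
class Beat:
    """One stimulus-aligned window containing a detected transient."""

    index: int  # stimulus index this beat belongs to
    time: np.ndarray  # s, window samples
    signal: np.ndarray  # normalized, polarity-corrected
    activation_time: float  # s, max first-difference after the stimulus
    baseline: float
    peak: float
    peak_time: float

    @property
    def amplitude(self) -> float:
        return self.peak - self.baseline


@dataclass
class BeatMetrics:
    """Duration/shape metrics for one beat (durations in ms)."""

    apd30: float = math.nan
    apd80: float = math.nan
    catd30: float = math.nan
    catd80: float = math.nan
    triangulation: float = math.nan
    amplitude: float = math.nan


@dataclass
class RhythmReport:
    """Entrainment/alternans classification of one channel of a record."""

    n_stimuli: int
    n_transients: int
    n_irregular: int
    entrained: bool
    alternans_ratio: float
    alternans_flag: bool


def normalize_dff(
    trace: TransientTrace,
    baseline_window: tuple[float, float] | None = None,
    polarity: dict | None = None,
) -> TransientTrace:
    """Return a dF/F0-normalized, polarity-corrected copy of the trace.

    F0 is the mean over ``baseline_window`` (default: everything before the
    first stimulus, or the first 3 frames if a stimulus sits at t=0). After
    normalization the baseline sits near 0 and upstrokes are positive.
    """
    polarity = dict(trace.polarity, **(polarity or {}))
    if baseline_window is None:
        t_first = trace.stimulus_times[0] if len(trace.stimulus_times) else trace.time[-1]
        if t_first <= trace.time[0] + 1e-12:
            baseline_window = (trace.time[0], trace.time[min(2, len(trace.time) - 1)])
        else:
            baseline_window = (trace.time[0], t_first)
    lo, hi = baseline_window
    mask = (trace.time >= lo) & (trace.time <= hi)
    if not mask.any():
        raise NormalizationError("empty baseline window")
    out = {}
    for name, sig in trace.channels.items():
        f0 = float(sig[mask].mean())
        if f0 <= 0:
            raise NormalizationError(f"channel {name!r}: baseline F0 = {f0} <= 0")
        out[name] = polarity.get(name, +1) * (sig - f0) / f0
    return TransientTrace(
        time=trace.time.copy(),
        channels=out,
        stimulus_times=trace.stimulus_times.copy(),
        polarity={name: +1 for name in out},
        truth=dict(trace.truth),
    )


def _baseline_noise_sd(signal: np.ndarray, time: np.ndarray, stim_times: np.ndarray) -> float:
    t_first = stim_times[0] if len(stim_times) else time[-1]
    mask = time < t_first
    seg = signal[mask] if mask.sum() >= 3 else signal[: max(3, len(signal) // 50)]
    return float(seg.std())


def segment_beats(
    trace: TransientTrace,
    channel: str,
    stimulus_times: Sequence[float] | None = None,
    detection_sigma: float = DETECTION_SIGMA,
) -> list[Beat]:
    """Split one channel into stimulus-aligned beats, keeping real transients.

    Windows are half-open ``[s_i, s_{i+1})`` (the last window runs to the end
    of the record). A beat is emitted only when the window's peak exceeds
    the pre-stimulus baseline by ``detection_sigma`` baseline-noise SDs (plus
    a tiny absolute floor for noiseless data); skipped beats therefore simply
    produce no entry. Activation time is the sample of maximum first
    difference after the stimulus.
    """
    stim = np.asarray(
        trace.stimulus_times if stimulus_times is None else stimulus_times, dtype=float
    )
    if len(stim) == 0:
        raise InvalidParameterError("at least one stimulus is required")
    signal = trace.channels[channel]
    time = trace.time
    noise_sd = _baseline_noise_sd(signal, time, stim)
    scale = max(float(np.ptp(signal)), 1e-12)

    beats: list[Beat] = []
    edges = np.concatenate([stim, [time[-1] + 1e-9]])
    for i in range(len(stim)):
        mask = (time >= edges[i]) & (time < edges[i + 1])
        if mask.sum() < 4:
            continue
        t_win = time[mask]
        s_win = signal[mask]
        # baseline from just before the stimulus: the first in-window sample
        # can already sit on the upstroke when the rise is sub-frame
        start = int(np.searchsorted(time, edges[i]))
        pre = signal[max(0, start - 3): start]
        baseline = float(np.median(pre)) if len(pre) else float(s_win[0])
        ipeak = int(np.argmax(s_win))
        peak = float(s_win[ipeak])
        # the window max of pure noise grows ~ sqrt(2 ln n); add that to the
        # detection margin so empty windows are not promoted to beats
        n_win = len(s_win)
        threshold = (
            detection_sigma + math.sqrt(2.0 * math.log(max(n_win, 2)))
        ) * noise_sd + 1e-3 * scale
        if peak - baseline < threshold:
            continue  # no transient evoked in this window
        dif = np.diff(s_win[: ipeak + 1]) if ipeak >= 1 else np.array([0.0])
        iact = int(np.argmax(dif))
        beats.append(
            Beat(
                index=i,
                time=t_win,
                signal=s_win,
                activation_time=float(t_win[iact]),
                baseline=baseline,
                peak=peak,
                peak_time=float(t_win[ipeak]),
            )
        )
    return beats


def duration_at_recovery(beat: Beat, fraction: float) -> float:
    """Time (ms) from activation to recovery of ``fraction`` of the amplitude.

    The crossing of level ``peak - fraction*(peak - baseline)`` after the
    peak is located with linear interpolation between samples, giving
    sub-frame precision at 100 frames/s. Returns NaN when the signal never
    recovers to that level inside the beat window (an "unrecovered" beat,
    counted as irregular upstream).
    """
    if beat.amplitude <= 0:
        raise InvalidMetricError("beat has non-positive amplitude")
    if not 0 < fraction <= 1:
        raise InvalidMetricError("fraction must be in (0, 1]")
    level = beat.peak - fraction * beat.amplitude
    ipeak = int(np.argmax(beat.signal))
    seg = beat.signal[ipeak:]
    below = np.nonzero(seg <= level)[0]
    if len(below) == 0:
        return math.nan
    j = below[0]
    if j == 0:
        t_cross = beat.time[ipeak]
    else:
        t0, t1 = beat.time[ipeak + j - 1], beat.time[ipeak + j]
        s0, s1 = seg[j - 1], seg[j]
        t_cross = t0 + (s0 - level) / (s0 - s1) * (t1 - t0)
    return (t_cross - beat.activation_time) * 1000.0


def triangulation_index(apd30: float, apd80: float) -> float:
    """Action-potential triangulation (APD80 - APD30)/APD80."""
    if not (0 < apd30 <= apd80):
        raise InvalidMetricError(f"need 0 < apd30 <= apd80, got {apd30}, {apd80}")
    return (apd80 - apd30) / apd80


def alternans_metric(peaks: Sequence[float]) -> tuple[float, bool]:
    """Even/odd alternans ratio of a per-beat peak sequence.

    ratio = |mean(even peaks) - mean(odd peaks)| / mean(all peaks); the flag
    is set above :data:`ALTERNANS_THRESHOLD`. The absolute difference makes
    the (arbitrary) choice of phase irrelevant.
    """
    p = np.asarray(peaks, dtype=float)
    if len(p) < 4:
        raise InsufficientDataError(f"alternans metric needs >= 4 peaks, got {len(p)}")
    ratio = abs(p[0::2].mean() - p[1::2].mean()) / p.mean()
    return float(ratio), bool(ratio > ALTERNANS_THRESHOLD)


def entrainment_check(
    trace: TransientTrace,
    channel: str,
    stimulus_times: Sequence[float] | None = None,
) -> RhythmReport:
    """Classify a channel's response to the stimulus train.

    The record is entrained when every stimulus evokes exactly one
    well-formed transient. ``n_irregular`` counts missed stimuli plus
    transients that never recover to the 80% level inside their window.
    """
    stim = np.asarray(
        trace.stimulus_times if stimulus_times is None else stimulus_times, dtype=float
    )
    beats = segment_beats(trace, channel, stimulus_times=stim)
    n_missed = len(stim) - len(beats)
    n_unrecovered = sum(1 for b in beats if math.isnan(duration_at_recovery(b, 0.80)))
    n_irregular = n_missed + n_unrecovered
    recovered = [b for b in beats if not math.isnan(duration_at_recovery(b, 0.80))]
    if len(recovered) >= 4:
        # phase by stimulus index, so missed beats cannot scramble even/odd
        even = [b.amplitude for b in recovered if b.index % 2 == 0]
        odd = [b.amplitude for b in recovered if b.index % 2 == 1]
        if even and odd:
            mean_all = float(np.mean([b.amplitude for b in recovered]))
            ratio = abs(float(np.mean(even)) - float(np.mean(odd))) / mean_all
            flag = ratio > ALTERNANS_THRESHOLD
        else:
            ratio, flag = math.nan, False
    else:
        ratio, flag = math.nan, False
    return RhythmReport(
        n_stimuli=len(stim),
        n_transients=len(beats),
        n_irregular=n_irregular,
        entrained=(n_irregular == 0),
        alternans_ratio=ratio,
        alternans_flag=flag,
    )


def beat_metrics_table(
    trace: TransientTrace,
    voltage_channel: str = "voltage",
    calcium_channel: str = "calcium",
    fractions: tuple[float, float] = (0.30, 0.80),
) -> pd.DataFrame:
    """Per-beat APD/CaTD/triangulation/amplitude table from a dual-channel trace.

    The trace should already be normalized (see :func:`normalize_dff`).
    Rows are indexed by stimulus number; a channel missing a transient at a
    stimulus leaves NaN metrics there.
    """
    f_lo, f_hi = fractions
    rows: dict[int, dict] = {}
    if voltage_channel in trace.channels:
        for b in segment_beats(trace, voltage_channel):
            lo = duration_at_recovery(b, f_lo)
            hi = duration_at_recovery(b, f_hi)
            tri = math.nan
            if not (math.isnan(lo) or math.isnan(hi)) and 0 < lo <= hi:
                tri = triangulation_index(lo, hi)
            rows.setdefault(b.index, {})[f"apd{int(f_lo * 100)}"] = lo
            rows[b.index][f"apd{int(f_hi * 100)}"] = hi
            rows[b.index]["triangulation"] = tri
            rows[b.index]["v_amplitude"] = b.amplitude
    if calcium_channel in trace.channels:
        for b in segment_beats(trace, calcium_channel):
            rows.setdefault(b.index, {})[f"catd{int(f_lo * 100)}"] = duration_at_recovery(b, f_lo)
            rows[b.index][f"catd{int(f_hi * 100)}"] = duration_at_recovery(b, f_hi)
            rows[b.index]["ca_amplitude"] = b.amplitude
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "beat"
    return df


def pcl_to_bpm(pcl_ms: float) -> float:
    """Pacing cycle length (ms) to beats per minute: 60000/PCL."""
    if pcl_ms <= 0:
        raise InvalidParameterError("PCL must be positive")
    return 60000.0 / pcl_ms


def bpm_to_pcl(bpm: float) -> float:
    """Beats per minute to pacing cycle length (ms): 60000/bpm."""
    if bpm <= 0:
        raise InvalidParameterError("rate must be positive")
    return 60000.0 / bpm


def summarize_by_frequency(
    metrics: pd.DataFrame,
    label_col: str = "label",
    rate_col: str = "rate_bpm",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SEM per (label, rate) and pairwise/across-rate tests.

    ``metrics`` is a long table with one row per beat, a genotype-style
    ``label`` column, a stimulation ``rate_bpm`` column and metric columns
    (any numeric column is summarized). Returns ``(summary, comparisons)``:
    the summary holds mean/sem/n per metric per cell; the comparisons hold
    unpaired two-group Student t tests between labels at each rate plus a
    one-way ANOVA across rates within each label with Tukey HSD pairs.
    """
    value_cols = [
        c
        for c in metrics.columns
        if c not in (label_col, rate_col) and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    summary_rows, comp_rows = [], []
    for (label, rate), grp in metrics.groupby([label_col, rate_col]):
        for col in value_cols:
            vals = grp[col].dropna()
            if len(vals) == 0:
                continue
            summary_rows.append(
                {
                    label_col: label,
                    rate_col: rate,
                    "metric": col,
                    "mean": vals.mean(),
                    "sem": vals.sem() if len(vals) >= 2 else math.nan,
                    "n": len(vals),
                }
            )
    labels = sorted(metrics[label_col].unique())
    # between-label Student t at each rate
    for rate, grp in metrics.groupby(rate_col):
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                for col in value_cols:
                    a = grp.loc[grp[label_col] == labels[i], col].dropna()
                    b = grp.loc[grp[label_col] == labels[j], col].dropna()
                    if len(a) < 2 or len(b) < 2:
                        continue
                    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
                        t_stat, p = 0.0, 1.0
                    else:
                        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
                    comp_rows.append(
                        {
                            "test": "student_t",
                            "metric": col,
                            rate_col: rate,
                            "group_a": labels[i],
                            "group_b": labels[j],
                            "stat": float(t_stat),
                            "p": float(p),
                            "significant": bool(p <= alpha),
                        }
                    )
    # across-rate ANOVA + Tukey within each label
    for label, grp in metrics.groupby(label_col):
        rates = sorted(grp[rate_col].unique())
        if len(rates) < 2:
            continue
        for col in value_cols:
            samples = [grp.loc[grp[rate_col] == r, col].dropna().to_numpy() for r in rates]
            samples = [s for s in samples if len(s) >= 2]
            if len(samples) < 2:
                continue
            if all(s.var(ddof=1) == 0 for s in samples) and len(
                {s.mean() for s in samples}
            ) == 1:
                f_stat, p = 0.0, 1.0
                tukey_p = np.ones((len(samples), len(samples)))
            else:
                f_stat, p = stats.f_oneway(*samples)
                tukey_p = stats.tukey_hsd(*samples).pvalue
            comp_rows.append(
                {
                    "test": "anova_rates",
                    "metric": col,
                    rate_col: math.nan,
                    "group_a": label,
                    "group_b": "|".join(str(r) for r in rates),
                    "stat": float(f_stat),
                    "p": float(p),
                    "significant": bool(p <= alpha),
                }
            )
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    comp_rows.append(
                        {
                            "test": "tukey",
                            "metric": col,
                            rate_col: math.nan,
                            "group_a": f"{label}@{rates[i]}",
                            "group_b": f"{label}@{rates[j]}",
                            "stat": math.nan,
                            "p": float(tukey_p[i, j]),
                            "significant": bool(tukey_p[i, j] <= alpha),
                        }
                    )
    return pd.DataFrame(summary_rows), pd.DataFrame(comp_rows)
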