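"""Steady-state and stopped-flow Ca2+ kinetics of reconstituted thin filaments.

Two in-vitro assays are modelled. A steady-state fluorescence titration
reports the Ca2+ sensitivity of the thin filament as the dissociation
constant ``Kd`` (the Ca2+ concentration at half-maximal fluorescence
change), obtained from a Hill fit

    F(Ca) = f_min + (f_max - f_min) * Ca^n / (Kd^n + Ca^n).

A stopped-flow EGTA-chase experiment reports the Ca2+ dissociation rate
``k_off`` from a single-exponential fit

    F(t) = A * exp(-k * t) + C

to the fluorescence decay, observed only after the instrument dead time.
Each assay is fitted per technical replicate and aggregated as
mean +/- SEM; constructs (e.g. wild type vs a troponin-T variant) are
compared with an unpaired pooled-variance Student t test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitFailureError, InsufficientDataError, InvalidParameterError

__all__ = [
    "TitrationDataset",
    "HillFitResult",
    "StoppedFlowDataset",
    "ExpDecayFitResult",
    "GroupComparison",
    "hill_curve",
    "exp_decay_curve",
    "fit_hill",
    "average_traces",
    "fit_exp_decay",
    "compare_parameters",
]


def hill_curve(ca, kd, hill_n, f_min, f_max):
    """Hill (sigmoidal) fluorescence-vs-Ca2+ curve; ``ca`` and ``kd`` in uM."""
    ca = np.asarray(ca, dtype=float)
    cn = ca**hill_n
    return f_min + (f_max - f_min) * cn / (kd**hill_n + cn)


def exp_decay_curve(t_ms, amplitude, k_per_ms, offset):
    """Single-exponential decay ``A*exp(-k t) + C`` with ``t`` in ms."""
    return amplitude * np.exp(-k_per_ms * np.asarray(t_ms, dtype=float)) + offset


@dataclass
class TitrationDataset:
    """A Ca2+ titration: fluorescence vs [Ca2+] for one construct.

    ``points`` is tidy with columns ``ca_uM``, ``fluor``, ``replicate``.
    """

    points: pd.DataFrame
    construct_label: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"ca_uM", "fluor", "replicate"}
        if not required.issubset(self.points.columns):
            raise InvalidParameterError(
                f"titration table needs columns {sorted(required)}"
            )
        if (self.points["ca_uM"] <= 0).any():
            raise InvalidParameterError("all Ca2+ concentrations must be > 0")
        counts = self.points.groupby("replicate")["ca_uM"].nunique()
        if (counts < 4).any():
            raise InvalidParameterError(
                "each replicate needs >= 4 distinct Ca2+ points for a Hill fit"
            )

    @property
    def replicates(self) -> list:
        return sorted(self.points["replicate"].unique().tolist())

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, construct_label: str = "") -> "TitrationDataset":
        return cls(pd.read_csv(path), construct_label=construct_label)


@dataclass
class HillFitResult:
    """Aggregated Hill fit: ``kd`` is the mean of per-replicate Kd values."""

    kd: float
    hill_n: float
    f_min: float
    f_max: float
    kd_sem: float  # NaN when only one replicate
    per_replicate_kd: list
    construct_label: str = ""

    def predict(self, ca):
        return hill_curve(ca, self.kd, self.hill_n, self.f_min, self.f_max)


@dataclass
class StoppedFlowDataset:
    """Stopped-flow decay traces; ``traces`` is tidy (t_ms, fluor, trace_id).

    Times start at the instrument dead time: the earlier part of the decay
    is physically unobservable.
    """

    traces: pd.DataFrame
    dead_time: float = 1.1  # ms
    construct_label: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"t_ms", "fluor", "trace_id"}
        if not required.issubset(self.traces.columns):
            raise InvalidParameterError(
                f"stopped-flow table needs columns {sorted(required)}"
            )
        for tid, grp in self.traces.groupby("trace_id"):
            t = grp["t_ms"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise InvalidParameterError(f"trace {tid}: times not strictly increasing")
            if t[0] < self.dead_time - 1e-9:
                raise InvalidParameterError(
                    f"trace {tid}: samples before the dead time ({self.dead_time} ms)"
                )

    @property
    def trace_ids(self) -> list:
        return sorted(self.traces["trace_id"].unique().tolist())

    @property
    def n_traces(self) -> int:
        return self.traces["trace_id"].nunique()

    def to_csv(self, path) -> None:
        self.traces.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dead_time: float = 1.1, construct_label: str = ""):
        return cls(pd.read_csv(path), dead_time=dead_time, construct_label=construct_label)


@dataclass
class ExpDecayFitResult:
    """Aggregated exponential fit; ``koff`` in s^-1."""

    koff: float
    amplitude: float
    offset: float
    koff_sem: float  # NaN when a single fit
    n_fits: int
    construct_label: str = ""


@dataclass
class GroupComparison:
    """Two-group unpaired Student t comparison of parameter estimates."""

    estimate_a: float
    estimate_b: float
    fold_ratio: float
    t_stat: float
    df: float
    p_value: float
    significant: bool
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Hill fitting


def _fit_hill_single(ca, fl, fix_hill_n=None):
    """Fit one replicate; multistart over Hill-coefficient seeds."""
    ca = np.asarray(ca, dtype=float)
    fl = np.asarray(fl, dtype=float)
    order = np.argsort(ca)
    ca, fl = ca[order], fl[order]

    f_lo, f_hi = float(fl.min()), float(fl.max())
    span = f_hi - f_lo if f_hi > f_lo else 1.0
    # Kd seed: Ca at half the observed span, by interpolation on the sorted curve
    half = f_lo + 0.5 * span
    kd0 = float(np.interp(half, fl, ca)) if fl[-1] > fl[0] else float(np.median(ca))
    kd0 = min(max(kd0, ca.min()), ca.max())

    n_seeds = [fix_hill_n] if fix_hill_n is not None else [1.0, 2.0, 0.5, 4.0]
    best, best_cost = None, np.inf
    errors = {}
    for n0 in n_seeds:
        if fix_hill_n is not None:
            def model(c, kd, fmin, fmax):
                return hill_curve(c, kd, fix_hill_n, fmin, fmax)

            p0 = [kd0, f_lo, f_hi]
            bounds = ([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        else:
            def model(c, kd, n, fmin, fmax):
                return hill_curve(c, kd, n, fmin, fmax)

            p0 = [kd0, n0, f_lo, f_hi]
            bounds = ([1e-9, 0.05, -np.inf, -np.inf], [np.inf, 20.0, np.inf, np.inf])
        try:
            popt, _ = optimize.curve_fit(model, ca, fl, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            errors[n0] = str(exc)
            continue
        resid = model(ca, *popt) - fl
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost = cost
            if fix_hill_n is not None:
                best = (popt[0], fix_hill_n, popt[1], popt[2])
            else:
                best = tuple(popt)
    if best is None:
        raise FitFailureError("Hill fit did not converge for any start", details=errors)
    return best  # (kd, n, f_min, f_max)


def fit_hill(data: TitrationDataset, fix_hill_n: float | None = None) -> HillFitResult:
    """Fit the Hill curve per replicate and aggregate Kd as mean +/- SEM.

    Each technical replicate (one full titration) is fitted independently;
    the reported ``kd`` is the across-replicate mean and ``kd_sem`` the
    standard error of that mean (NaN when only one replicate exists).
    Pass ``fix_hill_n`` to constrain the Hill coefficient.
    """
    per_kd, per_n, per_fmin, per_fmax = [], [], [], []
    diagnostics = {}
    for rep in data.replicates:
        grp = data.points[data.points["replicate"] == rep]
        try:
            kd, n, fmin, fmax = _fit_hill_single(
                grp["ca_uM"], grp["fluor"], fix_hill_n=fix_hill_n
            )
        except FitFailureError as exc:
            diagnostics[rep] = exc.details
            continue
        per_kd.append(kd)
        per_n.append(n)
        per_fmin.append(fmin)
        per_fmax.append(fmax)
    if not per_kd:
        raise FitFailureError("all replicate Hill fits failed", details=diagnostics)
    kd_arr = np.array(per_kd)
    sem = float(stats.sem(kd_arr)) if len(kd_arr) >= 2 else math.nan
    return HillFitResult(
        kd=float(kd_arr.mean()),
        hill_n=float(np.mean(per_n)),
        f_min=float(np.mean(per_fmin)),
        f_max=float(np.mean(per_fmax)),
        kd_sem=sem,
        per_replicate_kd=[float(k) for k in per_kd],
        construct_label=data.construct_label,
    )


# ---------------------------------------------------------------------------
# Stopped-flow fitting


def average_traces(data: StoppedFlowDataset) -> pd.DataFrame:
    """Pointwise mean of all traces on their common time grid.

    Traces sampled on different grids are linearly resampled onto the grid
    of the first trace restricted to the overlapping time range. Fewer than
    five traces triggers a warning (the averaged estimate is noisier than
    the protocol intends) but the mean is still returned.
    """
    ids = data.trace_ids
    if len(ids) < 5:
        warnings.warn(
            f"averaging only {len(ids)} stopped-flow traces (< 5)", stacklevel=2
        )
    groups = {tid: g.sort_values("t_ms") for tid, g in data.traces.groupby("trace_id")}
    t0 = groups[ids[0]]["t_ms"].to_numpy()
    t_lo = max(g["t_ms"].iloc[0] for g in groups.values())
    t_hi = min(g["t_ms"].iloc[-1] for g in groups.values())
    t = t0[(t0 >= t_lo - 1e-12) & (t0 <= t_hi + 1e-12)]
    acc = np.zeros_like(t, dtype=float)
    for tid in ids:
        g = groups[tid]
        acc += np.interp(t, g["t_ms"].to_numpy(), g["fluor"].to_numpy())
    return pd.DataFrame({"t_ms": t, "fluor": acc / len(ids)})


def _fit_exp_single(t_ms, fl):
    t = np.asarray(t_ms, dtype=float)
    f = np.asarray(fl, dtype=float)
    c0 = float(f[-max(1, len(f) // 20):].mean())
    a0 = float(f[0] - c0)
    # rate seed from the empirical half-decay time
    target = c0 + 0.5 * a0
    below = np.nonzero((f - target) * np.sign(a0) <= 0)[0]
    t_half = t[below[0]] - t[0] if len(below) else (t[-1] - t[0]) / 2
    k0 = math.log(2) / max(t_half, 1e-6)
    a0_at0 = a0 * math.exp(k0 * t[0])

    best, best_cost = None, np.inf
    errors = {}
    for k_seed in (k0, k0 * 5, k0 / 5):
        try:
            popt, _ = optimize.curve_fit(
                exp_decay_curve,
                t,
                f,
                p0=[a0_at0, k_seed, c0],
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # pragma: no cover
            errors[k_seed] = str(exc)
            continue
        resid = exp_decay_curve(t, *popt) - f
        cost = float(resid @ resid)
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise FitFailureError("exponential fit did not converge", details=errors)
    amplitude, k_per_ms, offset = best
    if amplitude <= 0:
        raise FitFailureError(
            "fitted amplitude <= 0: trace does not decay", details={"amplitude": amplitude}
        )
    return float(amplitude), float(k_per_ms), float(offset)


def fit_exp_decay(data: StoppedFlowDataset, average_first: bool = True) -> ExpDecayFitResult:
    """Fit ``F(t) = A exp(-k t) + C`` on the observed (post-dead-time) decay.

    With ``average_first`` the traces are averaged and a single fit is
    reported (``koff_sem`` NaN: the spread lives across repeated averaged
    sets, not within one). Without it, every trace is fitted and ``koff``
    is the across-trace mean +/- SEM. ``koff`` is returned in s^-1.
    """
    if average_first:
        avg = average_traces(data)
        amp, k, off = _fit_exp_single(avg["t_ms"], avg["fluor"])
        return ExpDecayFitResult(
            koff=k * 1000.0,
            amplitude=amp,
            offset=off,
            koff_sem=math.nan,
            n_fits=1,
            construct_label=data.construct_label,
        )
    ks, amps, offs = [], [], []
    diagnostics = {}
    for tid in data.trace_ids:
        grp = data.traces[data.traces["trace_id"] == tid]
        try:
            amp, k, off = _fit_exp_single(grp["t_ms"], grp["fluor"])
        except FitFailureError as exc:
            diagnostics[tid] = exc.details
            continue
        ks.append(k * 1000.0)
        amps.append(amp)
        offs.append(off)
    if not ks:
        raise FitFailureError("all per-trace exponential fits failed", details=diagnostics)
    ks = np.array(ks)
    sem = float(stats.sem(ks)) if len(ks) >= 2 else math.nan
    return ExpDecayFitResult(
        koff=float(ks.mean()),
        amplitude=float(np.mean(amps)),
        offset=float(np.mean(offs)),
        koff_sem=sem,
        n_fits=len(ks),
        construct_label=data.construct_label,
    )


# ---------------------------------------------------------------------------
# Construct comparison


def compare_parameters(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Unpaired pooled-variance Student t test between per-replicate estimates.

    ``fold_ratio`` is mean(a)/mean(b). Zero variance in both groups with
    equal means yields t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values for a t test")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(t_stat), float(p)
    return GroupComparison(
        estimate_a=float(a.mean()),
        estimate_b=float(b.mean()),
        fold_ratio=float(a.mean() / b.mean()),
        t_stat=t_stat,
        df=float(df),
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
    )
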