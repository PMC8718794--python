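"""Housekeeping-normalized count statistics for targeted expression panels.

Implements the analysis chain used for multiplexed digital-count panels
(NanoString-style): per-sample normalization against the geometric mean of
a housekeeping-gene set, per-gene Welch t tests on log2 expression between
two genotype groups, Benjamini-Yekutieli FDR correction (valid under
arbitrary dependence), and differential-expression calls at adjusted
p < alpha with no fold-change cutoff. A qPCR delta-delta-Ct fold-change
computation with geometric-mean reference normalization is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError, NormalizationError

__all__ = [
    "CountMatrix",
    "CtTable",
    "normalize_counts",
    "welch_test",
    "adjust_by",
    "call_degs",
    "deg_summary",
    "expression_ratio",
    "ddct_fold",
    "detection_filter",
]

DEFAULT_HOUSEKEEPING = ["PIK3CA", "ATP5F1", "IPO8", "PPIA", "SPCS1", "AKT", "RPS13"]


@dataclass
class CountMatrix:
    """Genes-by-samples count table with two-group labels.

    ``counts`` is a DataFrame indexed by gene with one column per sample;
    ``groups`` maps each sample to its group label (exactly two labels,
    each with >= 2 samples). ``negative_controls`` are optional background
    probes used by :func:`detection_filter`.
    """

    counts: pd.DataFrame
    groups: pd.Series
    housekeeping: list = field(default_factory=lambda: list(DEFAULT_HOUSEKEEPING))
    negative_controls: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.groups = pd.Series(self.groups)
        if not self.groups.index.equals(pd.Index(self.counts.columns)):
            self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise InvalidParameterError("every sample column needs a group label")
        sizes = self.groups.value_counts()
        if len(sizes) != 2 or (sizes < 2).any():
            raise InvalidParameterError("need exactly two groups with >= 2 samples each")
        missing = [g for g in self.housekeeping if g not in self.counts.index]
        if missing:
            raise InvalidParameterError(f"housekeeping genes absent from matrix: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidParameterError("counts must be non-negative")

    @property
    def group_labels(self) -> list:
        # stable order: first-seen label is the reference (control) group
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def to_csv(self, path) -> None:
        """Write genes x samples counts with a `group` header row."""
        header = pd.DataFrame([self.groups.values], index=["group"], columns=self.counts.columns)
        pd.concat([header, self.counts]).to_csv(path)

    @classmethod
    def from_csv(cls, path, housekeeping=None, negative_controls=None) -> "CountMatrix":
        raw = pd.read_csv(path, index_col=0)
        groups = raw.loc["group"]
        counts = raw.drop(index="group").astype(float)
        return cls(
            counts=counts,
            groups=groups,
            housekeeping=list(housekeeping) if housekeeping else list(DEFAULT_HOUSEKEEPING),
            negative_controls=list(negative_controls or []),
        )


@dataclass
class CtTable:
    """qPCR Ct values: tidy columns (gene, sample, group, ct)."""

    data: pd.DataFrame
    housekeeping: tuple = ("ACTB", "GAPDH")

    def __post_init__(self):
        required = {"gene", "sample", "group", "ct"}
        if not required.issubset(self.data.columns):
            raise InvalidParameterError(f"Ct table needs columns {sorted(required)}")
        if not np.isfinite(self.data["ct"]).all():
            raise InvalidParameterError("all Ct values must be finite")


def detection_filter(m: CountMatrix) -> CountMatrix:
    """Drop genes not detected above the negative-control background.

    A gene is kept when its mean count exceeds mean + 2 SD of the
    negative-control probes (a synthetic stand-in for proprietary
    cartridge background thresholding). With no negative controls the
    matrix is returned unchanged. Housekeeping genes are always kept.
    """
    if not m.negative_controls:
        return m
    neg = m.counts.loc[m.negative_controls].to_numpy().ravel()
    threshold = neg.mean() + 2.0 * neg.std(ddof=1 if len(neg) > 1 else 0)
    keep = (m.counts.mean(axis=1) > threshold) | m.counts.index.isin(m.housekeeping)
    keep &= ~m.counts.index.isin(m.negative_controls)
    return CountMatrix(
        counts=m.counts.loc[keep],
        groups=m.groups,
        housekeeping=m.housekeeping,
        negative_controls=[],
        truth=m.truth,
    )


def normalize_counts(m: CountMatrix) -> pd.DataFrame:
    """Housekeeping-geometric-mean normalization, then log2(x+1).

    Each sample's scale factor is the geometric mean of its housekeeping
    counts divided by the across-sample geometric mean of those values;
    dividing by the factor removes per-sample content/loading differences
    while leaving an all-identical matrix untouched.
    """
    hk = m.counts.loc[m.housekeeping]
    if (hk.to_numpy() <= 0).any():
        bad = hk.stack()[hk.stack() <= 0]
        gene, sample = bad.index[0]
        raise NormalizationError(
            f"housekeeping count <= 0 for gene {gene!r} in sample {sample!r}"
        )
    per_sample_gm = np.exp(np.log(hk).mean(axis=0))
    factors = per_sample_gm / np.exp(np.log(per_sample_gm).mean())
    normalized = m.counts.divide(factors, axis=1)
    return np.log2(normalized + 1.0)


def welch_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Welch unequal-variance t test: returns (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    se2a, se2b = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def adjust_by(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p values (input order preserved).

    adjusted(i) = min over j >= i (sorted order) of min(1, p(j) * m * c(m) / j)
    with c(m) = sum_{k=1..m} 1/k, the harmonic penalty that makes the
    procedure valid under arbitrary dependence between tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def call_degs(
    normalized: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene Welch tests with BY correction on a normalized log2 table.

    Fold change is oriented condition-vs-reference, where the reference is
    ``reference`` or the first-seen group label; ``log2_fc`` is the
    difference of group means on the log2 scale. A gene is significant at
    BY-adjusted p < alpha with no fold-change cutoff. Genes with missing
    values across a whole group are excluded (reported via the
    ``tested`` column set False).
    """
    groups = pd.Series(groups).reindex(normalized.columns)
    labels = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    if len(labels) != 2:
        raise InvalidParameterError("exactly two groups required")
    if reference is None:
        reference = labels[0]
    condition = labels[1] if reference == labels[0] else labels[0]
    cols_ref = groups.index[groups == reference]
    cols_cond = groups.index[groups == condition]

    rows = []
    for gene in normalized.index:
        ref_vals = normalized.loc[gene, cols_ref].dropna().to_numpy()
        cond_vals = normalized.loc[gene, cols_cond].dropna().to_numpy()
        if len(ref_vals) < 2 or len(cond_vals) < 2:
            rows.append(
                {"gene": gene, "tested": False, "log2_fc": math.nan, "t": math.nan,
                 "df": math.nan, "p": math.nan}
            )
            continue
        t, df, p = welch_test(cond_vals, ref_vals)
        rows.append(
            {
                "gene": gene,
                "tested": True,
                "log2_fc": float(cond_vals.mean() - ref_vals.mean()),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["p_adj"] = math.nan
    tested = table.index[table["tested"]]
    table.loc[tested, "p_adj"] = adjust_by(table.loc[tested, "p"].to_numpy())
    table["direction"] = np.where(table["log2_fc"] >= 0, "up", "down")
    table["significant"] = table["p_adj"] < alpha
    table.attrs["reference"] = reference
    table.attrs["condition"] = condition
    table.attrs["alpha"] = alpha
    return table


def deg_summary(table: pd.DataFrame) -> dict:
    """JSON-ready counts: genes tested, significant, up, down."""
    sig = table[table["significant"].fillna(False)]
    return {
        "n_tested": int(table["tested"].sum()),
        "n_significant": int(len(sig)),
        "n_up": int((sig["direction"] == "up").sum()),
        "n_down": int((sig["direction"] == "down").sum()),
        "reference": table.attrs.get("reference"),
        "condition": table.attrs.get("condition"),
        "alpha": table.attrs.get("alpha"),
    }


def expression_ratio(
    normalized: pd.DataFrame, gene_a: str, gene_b: str, samples: Sequence[str]
) -> float:
    """Linear-scale group-mean expression ratio gene_a/gene_b.

    Operates on the log2(x+1) normalized table by undoing the transform
    before averaging within the given sample set.
    """
    for g in (gene_a, gene_b):
        if g not in normalized.index:
            raise InvalidParameterError(f"gene {g!r} not in table")
    lin_a = (2.0 ** normalized.loc[gene_a, list(samples)] - 1.0).mean()
    lin_b = (2.0 ** normalized.loc[gene_b, list(samples)] - 1.0).mean()
    if lin_b == 0:
        raise InvalidParameterError(f"zero mean expression for denominator gene {gene_b!r}")
    return float(lin_a / lin_b)


def ddct_fold(
    ct: CtTable, target_gene: str, condition_group: str, reference_group: str
) -> float:
    """Delta-delta-Ct fold change of ``target_gene``, condition vs reference.

    Per sample, dCt = Ct(target) - mean Ct(housekeeping pair); the
    arithmetic Ct mean equals geometric-mean normalization on the linear
    scale. ddCt = mean dCt(condition) - mean dCt(reference); fold =
    2^(-ddCt).
    """
    data = ct.data
    missing = []
    dcts = {}
    for group in (condition_group, reference_group):
        sub = data[data["group"] == group]
        per_sample = []
        for sample, grp in sub.groupby("sample"):
            tgt = grp.loc[grp["gene"] == target_gene, "ct"]
            hks = [grp.loc[grp["gene"] == h, "ct"] for h in ct.housekeeping]
            if tgt.empty:
                missing.append((target_gene, sample))
                continue
            if any(h.empty for h in hks):
                missing.extend(
                    (ct.housekeeping[i], sample) for i, h in enumerate(hks) if h.empty
                )
                continue
            per_sample.append(float(tgt.iloc[0]) - float(np.mean([h.iloc[0] for h in hks])))
        dcts[group] = per_sample
    if missing:
        raise InvalidParameterError(f"missing Ct measurements: {sorted(set(missing))}")
    if not dcts[condition_group] or not dcts[reference_group]:
        raise InvalidParameterError("no complete samples in one of the groups")
    ddct = float(np.mean(dcts[condition_group]) - np.mean(dcts[reference_group]))
    return 2.0 ** (-ddct)
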