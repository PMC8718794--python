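"""Count normalization, Welch/BY statistics, DEG calling and ddCt folds."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from alternans import dge, synth
from alternans.exceptions import InvalidParameterError, NormalizationError


@pytest.fixture
def small_matrix():
    counts = pd.DataFrame(
        {
            "a1": [100, 200, 50, 400],
            "a2": [110, 190, 55, 390],
            "b1": [95, 210, 60, 800],
            "b2": [105, 205, 45, 820],
        },
        index=["HK1", "HK2", "G1", "G2"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return dge.CountMatrix(counts=counts, groups=groups, housekeeping=["HK1", "HK2"])


class TestNormalizeCounts:
    def test_identical_samples_pass_through(self):
        counts = pd.DataFrame(
            {f"s{i}": [10, 20, 30] for i in range(4)}, index=["HK1", "HK2", "G"]
        )
        m = dge.CountMatrix(
            counts=counts,
            groups=pd.Series(["A", "A", "B", "B"], index=counts.columns),
            housekeeping=["HK1", "HK2"],
        )
        out = dge.normalize_counts(m)
        np.testing.assert_allclose(out, np.log2(counts + 1), rtol=1e-12)

    def test_global_scaling_removed(self):
        """Samples that are scalar multiples of one another coincide after
        normalization (up to the +1 pseudocount at high counts)."""
        base = np.array([2000.0, 4000.0, 1000.0, 8000.0])
        factors = [1.0, 2.0, 0.5, 1.5]
        counts = pd.DataFrame(
            {f"s{i}": base * f for i, f in enumerate(factors)},
            index=["HK1", "HK2", "G1", "G2"],
        )
        m = dge.CountMatrix(
            counts, pd.Series(["A", "A", "B", "B"], index=counts.columns),
            housekeeping=["HK1", "HK2"],
        )
        out = dge.normalize_counts(m)
        for col in out.columns[1:]:
            np.testing.assert_allclose(out[col], out["s0"], rtol=1e-3)

    def test_zero_housekeeping_count_reported(self, small_matrix):
        bad = small_matrix.counts.copy()
        bad.loc["HK1", "a1"] = 0
        m = dge.CountMatrix(bad, small_matrix.groups, housekeeping=["HK1", "HK2"])
        with pytest.raises(NormalizationError, match="HK1.*a1"):
            dge.normalize_counts(m)

    def test_housekeeping_cv_shrinks_with_dispersion(self):
        cvs = []
        for disp in (0.2, 1e-4):
            m = synth.gen_counts(dispersion=disp, baseline_mean=20000.0, seed=3)
            norm = dge.normalize_counts(m)
            lin = 2.0 ** norm.loc[m.housekeeping] - 1.0
            cvs.append(float((lin.std(axis=1) / lin.mean(axis=1)).mean()))
        assert cvs[1] < cvs[0] / 3


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = dge.welch_test([10, 12, 14], [20, 22, 24])
        assert t == pytest.approx(-6.123724356957945, abs=1e-9)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert 0 < p < 0.01

    def test_identical_groups(self):
        t, _, p = dge.welch_test([1.0, 2.0], [1.0, 2.0])
        assert t == 0.0
        assert p == 1.0

    def test_swap_negates_t(self):
        t1, df1, p1 = dge.welch_test([1, 2, 3], [4, 6, 8])
        t2, df2, p2 = dge.welch_test([4, 6, 8], [1, 2, 3])
        assert t1 == -t2
        assert p1 == p2 and df1 == df2

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(1, 2, size=7)
        from scipy import stats

        t, df, p = dge.welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestAdjustBY:
    def test_single_p_unchanged(self):
        assert dge.adjust_by([0.031])[0] == pytest.approx(0.031)

    def test_hand_computed_step_up(self):
        """(0.01, 0.02, 0.9) with c(3)=11/6 adjusts to (0.055, 0.055, 1.0)."""
        np.testing.assert_allclose(
            dge.adjust_by([0.01, 0.02, 0.9]), [0.055, 0.055, 1.0], rtol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(dge.adjust_by([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            dge.adjust_by([0.5, 1.2])

    def test_monotone_bounded_and_above_bh(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        adj = dge.adjust_by(p)
        assert (adj <= 1.0).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        bh = multipletests(p, method="fdr_bh")[1]
        assert (adj >= bh - 1e-12).all()


class TestCallDegs:
    def test_injected_folds_called_significant(self):
        m = synth.gen_counts(seed=5)
        table = dge.call_degs(dge.normalize_counts(m), m.groups)
        for gene, fold in (("NPPA", 18.6), ("NPPB", 5.9)):
            row = table.loc[gene]
            assert row["significant"]
            assert row["direction"] == "up"
            assert row["log2_fc"] == pytest.approx(math.log2(fold), rel=0.25)

    def test_invariant_to_per_sample_rescaling(self):
        """Per-sample scale factors cancel (up to the +1 pseudocount)."""
        m = synth.gen_counts(baseline_mean=5000.0, seed=6)
        factors = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 0.8, 1.2])
        rescaled = dge.CountMatrix(
            counts=m.counts * factors, groups=m.groups, housekeeping=m.housekeeping
        )
        t1 = dge.call_degs(dge.normalize_counts(m), m.groups)
        t2 = dge.call_degs(dge.normalize_counts(rescaled), m.groups)
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-3, atol=1e-4)
        assert (t1["significant"] == t2["significant"]).all()

    def test_null_matrix_rarely_yields_calls(self):
        m = synth.gen_counts(fold_changes={}, seed=7)
        table = dge.call_degs(dge.normalize_counts(m), m.groups)
        assert int(table["significant"].sum()) == 0

    def test_adjusted_p_at_least_raw(self):
        m = synth.gen_counts(seed=8)
        table = dge.call_degs(dge.normalize_counts(m), m.groups)
        tested = table[table["tested"]]
        assert (tested["p_adj"] >= tested["p"] - 1e-15).all()


class TestDetectionFilter:
    def test_background_genes_dropped(self):
        m = synth.gen_counts(n_genes=30, baseline_mean=500.0, seed=9)
        counts = m.counts.copy()
        neg = pd.DataFrame(
            np.random.default_rng(0).poisson(5, size=(3, counts.shape[1])),
            index=["NEG1", "NEG2", "NEG3"], columns=counts.columns,
        )
        dim = pd.DataFrame(
            np.random.default_rng(1).poisson(4, size=(2, counts.shape[1])),
            index=["DIM1", "DIM2"], columns=counts.columns,
        )
        full = dge.CountMatrix(
            counts=pd.concat([counts, neg, dim]), groups=m.groups,
            housekeeping=m.housekeeping,
            negative_controls=["NEG1", "NEG2", "NEG3"],
        )
        kept = dge.detection_filter(full)
        assert "DIM1" not in kept.counts.index
        assert "NEG1" not in kept.counts.index
        assert set(m.housekeeping) <= set(kept.counts.index)


class TestExpressionRatio:
    def test_same_gene_gives_one(self, small_matrix):
        norm = dge.normalize_counts(small_matrix)
        assert dge.expression_ratio(norm, "G1", "G1", ["a1", "a2"]) == 1.0

    def test_known_ratio_recovered(self):
        m = synth.gen_counts(
            n_genes=20, fold_changes={}, dispersion=1e-5, baseline_mean=50000.0, seed=10
        )
        counts = m.counts.copy()
        counts.loc["TNNI3"] = counts.loc["GENE0000"] * 6.1
        counts.loc["TNNI1"] = counts.loc["GENE0000"]
        m2 = dge.CountMatrix(counts, m.groups, housekeeping=m.housekeeping)
        norm = dge.normalize_counts(m2)
        samples = m2.groups.index[m2.groups == m2.group_labels[0]]
        ratio = dge.expression_ratio(norm, "TNNI3", "TNNI1", samples)
        assert ratio == pytest.approx(6.1, rel=0.05)

    def test_scale_invariance(self, small_matrix):
        norm = dge.normalize_counts(small_matrix)
        r1 = dge.expression_ratio(norm, "G2", "G1", ["a1", "a2"])
        doubled_counts = small_matrix.counts.copy()
        doubled_counts.loc[["G1", "G2"]] *= 2
        m2 = dge.CountMatrix(
            doubled_counts, small_matrix.groups, housekeeping=["HK1", "HK2"]
        )
        r2 = dge.expression_ratio(dge.normalize_counts(m2), "G2", "G1", ["a1", "a2"])
        assert r2 == pytest.approx(r1, rel=0.02)


class TestDdct:
    @staticmethod
    def _ct_table(target_shift):
        rows = []
        for group, shift in (("WT", 0.0), ("variant", target_shift)):
            for s in range(3):
                sample = f"{group}_{s}"
                rows += [
                    {"gene": "ACTB", "sample": sample, "group": group, "ct": 18.0},
                    {"gene": "GAPDH", "sample": sample, "group": group, "ct": 20.0},
                    {"gene": "NPPA", "sample": sample, "group": group, "ct": 26.0 + shift},
                ]
        return dge.CtTable(pd.DataFrame(rows))

    def test_zero_ddct_gives_fold_one(self):
        fold = dge.ddct_fold(self._ct_table(0.0), "NPPA", "variant", "WT")
        assert fold == pytest.approx(1.0)

    def test_minus_one_ddct_gives_fold_two(self):
        fold = dge.ddct_fold(self._ct_table(-1.0), "NPPA", "variant", "WT")
        assert fold == pytest.approx(2.0)

    def test_fold_18_6_inverse(self):
        fold = dge.ddct_fold(self._ct_table(-math.log2(18.6)), "NPPA", "variant", "WT")
        assert fold == pytest.approx(18.6, rel=1e-9)

    def test_missing_measurement_listed(self):
        table = self._ct_table(0.0)
        data = table.data[~((table.data["gene"] == "GAPDH") & (table.data["sample"] == "WT_0"))]
        with pytest.raises(InvalidParameterError, match="GAPDH"):
            dge.ddct_fold(dge.CtTable(data), "NPPA", "variant", "WT")


def test_count_matrix_csv_round_trip(tmp_path):
    m = synth.gen_counts(n_genes=15, seed=11)
    path = tmp_path / "counts.csv"
    m.to_csv(path)
    back = dge.CountMatrix.from_csv(path)
    pd.testing.assert_frame_equal(back.counts, m.counts)
    assert (back.groups == m.groups).all()


def test_matrix_validation():
    counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]}, index=["PPIA", "G"])
    with pytest.raises(InvalidParameterError):
        dge.CountMatrix(counts, pd.Series(["A", "B"], index=["a", "b"]), housekeeping=["PPIA"])
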