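"""Transient-trace metrics: normalization, segmentation, durations, rhythm."""

import math

import numpy as np
import pandas as pd
import pytest

from alternans import synth, traces
from alternans.exceptions import (
    InsufficientDataError,
    InvalidMetricError,
    InvalidParameterError,
    NormalizationError,
)


def make_linear_decay_beat(decay_ms=100.0, dt_ms=1.0):
    """Instantaneous-rise pulse decaying linearly to baseline over decay_ms."""
    t = np.arange(0.0, decay_ms + 50.0, dt_ms) / 1000.0
    sig = np.clip(1.0 - (t * 1000.0) / decay_ms, 0.0, None)
    return traces.Beat(
        index=0, time=t, signal=sig, activation_time=0.0,
        baseline=0.0, peak=1.0, peak_time=0.0,
    )


class TestNormalizeDff:
    def test_constant_trace_maps_to_zero(self):
        trace = traces.TransientTrace(
            time=np.arange(0, 2, 0.01),
            channels={"calcium": np.full(200, 40.0)},
            stimulus_times=np.array([1.0]),
        )
        out = traces.normalize_dff(trace)
        np.testing.assert_allclose(out.channels["calcium"], 0.0, atol=1e-12)

    def test_polarity_flip_equivalence(self):
        up = synth.gen_transient_train(rate=60, duration=5, noise_sd=0.0, polarity=+1)
        down = synth.gen_transient_train(rate=60, duration=5, noise_sd=0.0, polarity=-1)
        nu = traces.normalize_dff(up)
        nd = traces.normalize_dff(down)
        np.testing.assert_allclose(
            nu.channels["voltage"], nd.channels["voltage"], atol=1e-9
        )

    def test_nonpositive_baseline_rejected(self):
        trace = traces.TransientTrace(
            time=np.arange(0, 2, 0.01),
            channels={"calcium": np.full(200, -1.0)},
            stimulus_times=np.array([1.0]),
        )
        with pytest.raises(NormalizationError):
            traces.normalize_dff(trace)

    def test_affine_transform_leaves_metrics_unchanged(self):
        """Metrics after dF/F are invariant to a*F + b on the raw trace."""
        trace = synth.gen_transient_train(rate=60, duration=8, noise_sd=0.0)
        table_ref = traces.beat_metrics_table(traces.normalize_dff(trace))
        scaled = traces.TransientTrace(
            time=trace.time,
            channels={k: 2.5 * v + 10.0 for k, v in trace.channels.items()},
            stimulus_times=trace.stimulus_times,
        )
        table_scaled = traces.beat_metrics_table(traces.normalize_dff(scaled))
        for col in ("apd30", "apd80", "catd30", "catd80", "triangulation"):
            np.testing.assert_allclose(
                table_scaled[col].dropna(), table_ref[col].dropna(), rtol=1e-6
            )


class TestSegmentBeats:
    def test_clean_train_gives_one_beat_per_stimulus(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(rate=60, duration=20, noise_sd=0.0)
        )
        beats = traces.segment_beats(trace, "calcium")
        assert len(beats) == 20

    def test_flat_trace_gives_no_beats(self):
        trace = traces.TransientTrace(
            time=np.arange(0, 5, 0.01),
            channels={"calcium": np.zeros(500)},
            stimulus_times=np.arange(0.5, 4.5, 1.0),
        )
        assert traces.segment_beats(trace, "calcium") == []

    def test_skipped_beats_missing_at_right_indices(self):
        skipped = [1, 4, 7]
        trace = traces.normalize_dff(
            synth.gen_transient_train(
                rate=60, duration=10, noise_sd=0.005, skipped_beats=skipped, seed=3
            )
        )
        beats = traces.segment_beats(trace, "calcium")
        present = {b.index for b in beats}
        assert present == set(range(10)) - set(skipped)


class TestDurationAtRecovery:
    def test_linear_decay_ramp(self):
        beat = make_linear_decay_beat(decay_ms=100.0)
        assert traces.duration_at_recovery(beat, 0.30) == pytest.approx(30.0, abs=1e-9)
        assert traces.duration_at_recovery(beat, 0.80) == pytest.approx(80.0, abs=1e-9)

    def test_full_recovery_fraction_one(self):
        beat = make_linear_decay_beat(decay_ms=100.0)
        assert traces.duration_at_recovery(beat, 1.0) == pytest.approx(100.0, abs=1e-9)

    def test_unrecovered_beat_returns_nan(self):
        t = np.arange(0.0, 0.2, 0.01)
        beat = traces.Beat(
            index=0, time=t, signal=np.full_like(t, 1.0), activation_time=0.0,
            baseline=0.0, peak=1.0, peak_time=0.0,
        )
        assert math.isnan(traces.duration_at_recovery(beat, 0.8))


class TestTriangulation:
    @pytest.mark.parametrize(
        "apd30,apd80,expected", [(210, 300, 0.30), (100, 250, 0.60), (250, 250, 0.0)]
    )
    def test_formula(self, apd30, apd80, expected):
        assert traces.triangulation_index(apd30, apd80) == pytest.approx(expected)

    def test_inverted_durations_rejected(self):
        with pytest.raises(InvalidMetricError):
            traces.triangulation_index(300, 210)


class TestAlternansMetric:
    def test_known_period_two_sequence(self):
        ratio, flag = traces.alternans_metric([1.2, 0.8, 1.2, 0.8])
        assert ratio == pytest.approx(0.4)
        assert flag

    def test_constant_sequence(self):
        ratio, flag = traces.alternans_metric([1.0] * 8)
        assert ratio == 0.0
        assert not flag

    def test_too_few_peaks(self):
        with pytest.raises(InsufficientDataError):
            traces.alternans_metric([1.0, 2.0, 1.0])

    def test_matches_phase_enumeration_oracle(self):
        """Equals the brute-force best-phase even/odd separation."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            peaks = rng.uniform(0.5, 1.5, size=rng.integers(4, 12))
            ratio, _ = traces.alternans_metric(peaks)
            best = max(
                abs(peaks[0::2].mean() - peaks[1::2].mean()),
                abs(np.roll(peaks, 1)[0::2].mean() - np.roll(peaks, 1)[1::2].mean())
                if len(peaks) % 2 == 0
                else abs(peaks[1::2].mean() - peaks[0::2].mean()),
            )
            assert ratio <= best / peaks.mean() + 1e-12

    def test_injected_ratio_recovered_through_pipeline(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(
                rate=100, duration=20, alternans_ratio=0.2, noise_sd=0.02,
                apd30=150, apd80=250, catd30=180, catd80=300, seed=9,
            )
        )
        report = traces.entrainment_check(trace, "calcium")
        assert report.alternans_ratio == pytest.approx(0.2, abs=0.02)
        assert report.alternans_flag


class TestEntrainment:
    def test_clean_train_is_entrained(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(rate=55, duration=20, noise_sd=0.0)
        )
        report = traces.entrainment_check(trace, "calcium")
        assert report.entrained
        assert report.n_irregular == 0

    def test_eight_skipped_transients_counted(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(
                rate=100, duration=20, noise_sd=0.005,
                skipped_beats=[3, 6, 9, 13, 17, 21, 25, 29], seed=4,
            )
        )
        report = traces.entrainment_check(trace, "calcium")
        assert report.n_stimuli == 33
        assert report.n_irregular == 8
        assert not report.entrained

    def test_two_to_one_response(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(
                rate=100, duration=20, noise_sd=0.0,
                skipped_beats=list(range(1, 33, 2)), seed=0,
            )
        )
        report = traces.entrainment_check(trace, "calcium")
        assert report.n_transients == report.n_stimuli - 16


class TestRateConversion:
    @pytest.mark.parametrize("pcl,bpm", [(500, 120), (600, 100), (1000, 60)])
    def test_known_values(self, pcl, bpm):
        assert traces.pcl_to_bpm(pcl) == bpm

    def test_round_trip_identity(self):
        for x in (55.0, 65.0, 75.0, 100.0, 150.0):
            assert traces.pcl_to_bpm(traces.bpm_to_pcl(x)) == pytest.approx(x, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            traces.pcl_to_bpm(0)


class TestRoundTrip:
    @pytest.mark.parametrize("rate", [55.0, 75.0, 100.0])
    def test_noiseless_metric_recovery(self, rate):
        """Requested durations recovered within one 10-ms frame interval."""
        req = dict(apd30=160.0, apd80=260.0, catd30=200.0, catd80=330.0)
        trace = traces.normalize_dff(
            synth.gen_transient_train(rate=rate, duration=12, noise_sd=0.0, **req)
        )
        table = traces.beat_metrics_table(trace).iloc[1:-1]
        for key, want in req.items():
            got = table[key].dropna()
            assert len(got) > 0
            assert np.max(np.abs(got - want)) < 10.0

    def test_duration_ordering_invariant(self):
        trace = traces.normalize_dff(
            synth.gen_transient_train(rate=65, duration=15, noise_sd=0.01, seed=2)
        )
        table = traces.beat_metrics_table(trace).dropna()
        assert (table["apd30"] <= table["apd80"]).all()
        assert (table["catd30"] <= table["catd80"]).all()


class TestSummarize:
    @staticmethod
    def _metric_frame(offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for label, shift in (("WT", 0.0), ("variant", offset)):
            for rate in (55, 65, 75):
                for _ in range(10):
                    rows.append(
                        {
                            "label": label,
                            "rate_bpm": rate,
                            "apd80": 300 - rate + shift + rng.normal(0, 5),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        df = self._metric_frame(offset=0.0)
        df.loc[df["label"] == "variant", "apd80"] = df.loc[
            df["label"] == "WT", "apd80"
        ].to_numpy()
        _, comps = traces.summarize_by_frequency(df)
        t_tests = comps[comps["test"] == "student_t"]
        assert np.allclose(t_tests["p"], 1.0)

    def test_large_offset_is_significant(self):
        _, comps = traces.summarize_by_frequency(self._metric_frame(offset=50.0))
        t_tests = comps[comps["test"] == "student_t"]
        assert t_tests["significant"].all()

    def test_summary_contains_mean_sem_n(self):
        summary, _ = traces.summarize_by_frequency(self._metric_frame())
        assert {"mean", "sem", "n"} <= set(summary.columns)
        assert (summary["n"] == 10).all()

    def test_anova_null_type_i_rate(self):
        """One-way ANOVA across equal-mean rates rejects at ~alpha."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 400
        from scipy import stats as sps

        for _ in range(n_sim):
            groups = [rng.normal(size=8) for _ in range(3)]
            if sps.f_oneway(*groups).pvalue <= 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.03)


def test_csv_round_trip(tmp_path):
    trace = synth.gen_transient_train(rate=60, duration=5, noise_sd=0.01, seed=8)
    path = tmp_path / "train.csv"
    trace.to_csv(path)
    back = traces.TransientTrace.from_csv(path)
    np.testing.assert_allclose(back.time, trace.time)
    np.testing.assert_allclose(back.channels["calcium"], trace.channels["calcium"])
    np.testing.assert_allclose(back.stimulus_times, trace.stimulus_times)
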