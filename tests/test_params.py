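"""Stride parameters, validation statistics, and morphology."""

import numpy as np
import pytest

from insolegait.params import (
    agreement_stats, per_minute_summary, percentage_stance, rmse, stride_count_accuracy,
    stride_metrics, stride_morphology, stride_times,
)
from insolegait.segment import FsrSumSeries, GaitEvent, GaitEventList


def _events(*pairs):
    return GaitEventList([GaitEvent(k, t, int(round(t * 100))) for k, t in pairs])


class TestStrideTimes:
    def test_consecutive_differences(self):
        ev = _events(("HS", 0.0), ("HS", 1.2), ("HS", 2.4))
        np.testing.assert_allclose(stride_times(ev), [1.2, 1.2])

    def test_single_event_empty(self):
        assert stride_times(_events(("HS", 0.0))).size == 0

    def test_partial_events_excluded(self):
        ev = GaitEventList([
            GaitEvent("HS", 0.0, 0, partial=True),
            GaitEvent("HS", 1.0, 100), GaitEvent("HS", 2.1, 210),
        ])
        np.testing.assert_allclose(stride_times(ev), [1.1])

    def test_session_matches_truth_differences(self, session_3kmh, segmented_3kmh):
        events, _ = segmented_3kmh
        st = stride_times(events)
        st_truth = np.diff(session_3kmh.truth_events.times("HS"))
        np.testing.assert_allclose(st, st_truth, atol=2.0 / session_3kmh.fsr.fs)

    def test_telescoping_identity(self, segmented_3kmh):
        events, _ = segmented_3kmh
        hs = events.times("HS")
        st = stride_times(events)
        assert st.mean() == pytest.approx((hs[-1] - hs[0]) / (hs.size - 1))


class TestPercentageStance:
    @pytest.mark.parametrize("to_t,expected", [(0.7, 70.0), (0.5, 50.0)])
    def test_simple_ratio(self, to_t, expected):
        ev = _events(("HS", 0.0), ("TO", to_t), ("HS", 1.0))
        assert percentage_stance(ev)[0] == pytest.approx(expected)

    def test_shift_and_scale_invariance(self):
        base = [("HS", 0.0), ("TO", 0.66), ("HS", 1.1), ("TO", 1.75), ("HS", 2.2)]
        ref = percentage_stance(_events(*base))
        shifted = percentage_stance(_events(*[(k, t + 17.3) for k, t in base]))
        scaled = percentage_stance(_events(*[(k, t * 4.2) for k, t in base]))
        np.testing.assert_allclose(shifted, ref)
        np.testing.assert_allclose(scaled, ref)

    def test_non_alternating_rejected(self):
        with pytest.raises(ValueError):
            percentage_stance(_events(("HS", 0.0), ("HS", 1.0), ("TO", 1.5)))

    def test_session_mean_near_reference_value(self, segmented_3kmh):
        events, _ = segmented_3kmh
        assert abs(percentage_stance(events).mean() - 68.20) <= 2.0


class TestScalarStats:
    @pytest.mark.parametrize("test,ref,expected", [
        (99, 100, 99.0), (50, 50, 100.0), (29, 30, pytest.approx(96.667, abs=1e-3)),
    ])
    def test_stride_count_accuracy(self, test, ref, expected):
        assert stride_count_accuracy(test, ref) == expected

    def test_accuracy_requires_reference(self):
        with pytest.raises(ValueError):
            stride_count_accuracy(10, 0)

    def test_rmse_examples(self, rng):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 3.0], [4.0, 3.0]) == pytest.approx(np.sqrt(8.0))
        a, b = rng.normal(size=40), rng.normal(size=40)
        brute = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 40)
        assert rmse(a, b) == pytest.approx(brute)
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestAgreement:
    def test_identical_series(self, rng):
        x = rng.normal(size=30)
        st = agreement_stats(x, x)
        assert st.bias == 0.0 and st.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self, rng):
        x = rng.normal(size=30)
        st = agreement_stats(x + 1.0, x)
        assert st.bias == pytest.approx(1.0)
        assert st.loa_high - st.loa_low == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_formulas(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        st = agreement_stats(x, y)
        d = x - y
        assert st.bias == pytest.approx(d.mean())
        assert st.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert st.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_zero_variance_r_missing(self):
        st = agreement_stats(np.ones(5), np.arange(5.0))
        assert np.isnan(st.pearson_r)


class TestMorphology:
    def _flat_cycles(self, gains, cycle_len=100):
        values = np.concatenate([np.full(cycle_len, 10.0 * g) for g in gains])
        hs = [("HS", i * cycle_len / 100.0) for i in range(len(gains) + 1)]
        return FsrSumSeries(fs=100.0, values=values), _events(*hs)

    def test_identical_strides_zero_cov(self):
        s, ev = self._flat_cycles([1.0] * 5)
        m = stride_morphology(s, ev)
        np.testing.assert_allclose(m.std_curve, 0.0)
        assert m.cov == 0.0

    def test_multiplicative_gain_cov_matches_cv(self, rng):
        gains = rng.normal(1.0, 0.1, size=200)
        s, ev = self._flat_cycles(gains)
        m = stride_morphology(s, ev)
        assert m.cov == pytest.approx(gains.std(ddof=1) / gains.mean(), rel=1e-6)
        assert m.cov == pytest.approx(0.1, abs=0.02)

    def test_too_few_cycles_rejected(self):
        s, ev = self._flat_cycles([1.0])
        with pytest.raises(ValueError):
            stride_morphology(s, ev)

    def test_session_cov_plausible_for_fsr_insole(self, session_3kmh, segmented_3kmh):
        from insolegait.segment import sum_fsr
        events, _ = segmented_3kmh
        m = stride_morphology(sum_fsr(session_3kmh.fsr), events)
        assert 0.05 <= m.cov <= 0.2  # same order as reported insole variability (~0.1)


class TestAggregation:
    def test_stride_metrics_counts(self, session_3kmh, segmented_3kmh):
        events, _ = segmented_3kmh
        m = stride_metrics(events)
        assert m.nos == session_3kmh.truth_events.times("HS").size
        assert m.cadence_spm == pytest.approx(60.0 / m.mean_stride_time_s)

    def test_per_minute_bins(self):
        hs = [("HS", 0.5 + 1.0 * i) for i in range(130)]
        rows = per_minute_summary(_events(*hs), bin_s=60.0)
        assert len(rows) == 3
        assert rows[0]["n_strides"] == 60
        assert rows[0]["mean_stride_time_s"] == pytest.approx(1.0)
        assert rows[0]["cadence_spm"] == pytest.approx(60.0)
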