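import math

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from emg2gait import (GaitEvent, GaitTemplate, LagGrid, ParameterError,
                      TrialMetrics, UndefinedCorrelationError, aggregate,
                      correlogram, evaluate_trial, event_rates,
                      events_to_phases, generate_cycle_train, match_events,
                      pearson_r, phase_f1, phase_f1_detail)
from emg2gait.events import PhaseSeries
from conftest import make_channel


def optimal_assignment_cardinality(tt, tp, max_ms=600.0):
    """Brute-force oracle: maximum-cardinality one-to-one matching under the
    distance constraint, via the Hungarian algorithm with big-M costs."""
    if not len(tt) or not len(tp):
        return 0
    d = np.abs(np.subtract.outer(tt, tp)) * 1000.0
    big = 1e9
    cost = np.where(d < max_ms, d, big)
    rows, cols = linear_sum_assignment(cost)
    return int(np.sum(cost[rows, cols] < big))


class TestPearson:
    def test_identity_and_negation(self, rng):
        x = rng.standard_normal(100)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, rng):
        a = rng.standard_normal(500)
        b = 0.3 * a + rng.standard_normal(500)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert pearson_r(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_nan_samples_excluded_jointly(self, rng):
        a = rng.standard_normal(100)
        b = a.copy()
        a2 = a.copy()
        a2[:10] = np.nan
        assert pearson_r(a2, b) == pytest.approx(1.0)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestMatchEvents:
    def test_identical_lists(self):
        t = [1.0, 2.1, 3.2]
        m = match_events(t, t)
        assert len(m.matches) == 3
        assert m.displacements_ms().max() == 0.0
        assert event_rates(m) == (0.0, 0.0)

    def test_uniform_shift(self):
        t = np.arange(10) * 1.1
        m = match_events(t, t + 0.1)
        assert len(m.matches) == 10
        np.testing.assert_allclose(m.displacements_ms(), 100.0)
        np.testing.assert_allclose(m.displacements_ms(absolute=False), 100.0)

    def test_beyond_tolerance_unmatched(self):
        m = match_events([1.0], [1.7])
        assert not m.matches
        assert m.misses == [1.0] and m.false_detections == [1.7]

    def test_greedy_equals_optimal_assignment(self, rng):
        """On jittered/deleted/inserted gait-like event trains of up to 10
        events, greedy nearest-pair matching reaches the optimal
        cardinality.  (The guarantee is empirical and specific to trains
        whose spacing dwarfs the matching tolerance; it does not extend to
        arbitrary dense event sets.)"""
        for _ in range(300):
            n = rng.integers(2, 10)
            tt = 0.5 + np.cumsum(1.1 + rng.normal(0, 0.05, n))
            keep = rng.random(n) > 0.2
            tp = tt[keep] + rng.normal(0, 0.1, keep.sum())
            ins = rng.uniform(tt[0] - 0.5, tt[-1] + 0.5, rng.integers(0, 3))
            tp = np.sort(np.concatenate([tp, ins]))
            m = match_events(tt, tp)
            assert len(m.matches) == optimal_assignment_cardinality(tt, tp)

    def test_swap_symmetry(self, rng):
        tt = np.sort(rng.uniform(0, 10, 8))
        tp = np.sort(rng.uniform(0, 10, 6))
        m1 = match_events(tt, tp)
        m2 = match_events(tp, tt)
        assert len(m1.matches) == len(m2.matches)
        assert m1.misses == m2.false_detections
        assert m1.false_detections == m2.misses

    def test_mixed_types_rejected(self):
        a = [GaitEvent(type="HC", leg="left", time_s=1.0),
             GaitEvent(type="TO", leg="left", time_s=2.0)]
        with pytest.raises(ParameterError):
            match_events(a, a)


class TestEventRates:
    def test_arithmetic(self):
        tt = np.arange(100) * 1.0
        tp = np.concatenate([tt[:98] + 0.01, [1000.0, 1001.5]])
        m = match_events(tt, tp)
        fdr, fnr = event_rates(m)
        assert fdr == pytest.approx(0.02)
        assert fnr == pytest.approx(0.02)

    def test_no_predictions(self):
        m = match_events([1.0, 2.0], [])
        fdr, fnr = event_rates(m)
        assert fnr == 1.0 and math.isnan(fdr)

    def test_simulated_deletion_rate(self, rng):
        tt = np.arange(1000) * 1.1
        keep = rng.random(1000) > 0.02
        fdr, fnr = event_rates(match_events(tt, tt[keep]))
        assert fdr == 0.0
        assert fnr == pytest.approx(0.02, abs=0.01)


class TestPhaseF1:
    def _series(self, labels, defined=None, leg="left"):
        labels = np.asarray(labels, bool)
        if defined is None:
            defined = np.ones_like(labels)
        return PhaseSeries(leg=leg, labels=labels,
                           defined=np.asarray(defined, bool), fs=200.0)

    def test_identical_series(self, rng):
        lab = rng.random(500) > 0.5
        assert phase_f1(self._series(lab), self._series(lab)) == 1.0

    def test_all_stance_prediction_zero_recall(self):
        true = self._series([0, 1, 1, 0, 1])
        pred = self._series([0, 0, 0, 0, 0])
        assert phase_f1(true, pred) == 0.0

    def test_confusion_matrix_oracle(self, rng):
        from sklearn.metrics import f1_score
        a = rng.random(1000) > 0.4
        b = rng.random(1000) > 0.4
        mine = phase_f1_detail(self._series(a), self._series(b))
        assert mine["f1_swing"] == pytest.approx(
            f1_score(a, b, pos_label=1), abs=1e-12)
        assert mine["f1_stance"] == pytest.approx(
            f1_score(a, b, pos_label=0), abs=1e-12)

    def test_empty_joint_mask_undefined(self):
        t = self._series([0, 1], defined=[1, 0])
        p = self._series([0, 1], defined=[0, 1])
        assert math.isnan(phase_f1(t, p))


class TestCorrelogram:
    def test_zero_lag_identity(self, rng):
        x = rng.standard_normal(4000)
        emg = make_channel(x, kind="emg", label="LVl")
        imu = make_channel(x)
        cg = correlogram(emg, imu)
        k0 = int(np.where(cg.lags_ms == 0.0)[0][0])
        assert cg.r_values[k0] == pytest.approx(1.0)
        assert cg.peak_lag_ms == 0.0

    def test_planted_delay_recovered(self, rng):
        """EMG that lags the IMU trace by 150 ms peaks at +150 ms."""
        y = rng.standard_normal(6000)
        delayed = np.roll(y, 30)  # 150 ms at 200 Hz
        emg = make_channel(delayed + 0.05 * rng.standard_normal(6000),
                           kind="emg", label="LVl")
        cg = correlogram(emg, make_channel(y))
        assert cg.peak_lag_ms == 150.0

    def test_white_noise_rarely_significant(self, rng):
        emg = make_channel(rng.standard_normal(10000), kind="emg", label="LVl")
        imu = make_channel(rng.standard_normal(10000))
        cg = correlogram(emg, imu)
        assert np.max(np.abs(cg.r_values)) < 0.05
        assert cg.significant.sum() == 0


class TestEvaluateTrial:
    def _trace(self, rng, noise=0.0):
        ch, _, _ = generate_cycle_train(GaitTemplate(), 30.0, rng, fs=200.0,
                                        cycle_jitter_ms=10.0, noise_sd=noise)
        return ch

    def test_perfect_prediction(self, rng):
        av = self._trace(rng)
        tm = evaluate_trial(av, av)
        assert tm.pearson == pytest.approx(1.0)
        assert tm.f1 == 1.0
        for etype in ("SWP", "HC", "TO"):
            d = tm.per_type[etype]
            assert d["median_abs_displacement_ms"] == 0.0
            assert d["fdr"] == 0.0 and d["fnr"] == 0.0

    def test_uniform_50ms_shift(self, rng):
        av = self._trace(rng)
        shifted = av.with_samples(np.roll(av.samples, 10))  # +50 ms
        tm = evaluate_trial(av, shifted)
        for etype in ("SWP", "HC", "TO"):
            assert tm.per_type[etype]["median_abs_displacement_ms"] == \
                pytest.approx(50.0, abs=5.0)

    def test_common_shift_leaves_metrics_invariant(self, rng):
        av = self._trace(rng, noise=1.0)
        pred = av.with_samples(av.samples + 0.5 * np.roll(av.samples, 4)
                               - 0.5 * av.samples)
        base = evaluate_trial(av, pred)
        k = 40
        av2 = av.with_samples(av.samples[k:])
        pred2 = pred.with_samples(pred.samples[k:])
        shifted = evaluate_trial(av2, pred2)
        assert shifted.f1 == pytest.approx(base.f1, abs=0.02)
        for etype in ("SWP", "HC", "TO"):
            assert shifted.per_type[etype]["fnr"] == \
                pytest.approx(base.per_type[etype]["fnr"], abs=0.05)


class TestAggregate:
    def test_single_trial_summary_equals_trial(self, rng):
        ch, _, _ = generate_cycle_train(GaitTemplate(), 20.0, rng, fs=200.0)
        tm = evaluate_trial(ch, ch, patient_id="P01", trial_id="T01")
        s = aggregate([tm])
        assert s["pearson_r"]["median"] == tm.pearson
        assert s["f1"]["median"] == tm.f1
        assert s["n_trials"] == 1

    def test_known_median(self):
        vals = [0.8, 0.85, 0.9]
        base = None
        metrics = []
        for i, v in enumerate(vals):
            per_type = {e: {"median_abs_displacement_ms": 10.0,
                            "iqr_low_ms": 5.0, "iqr_high_ms": 15.0,
                            "fdr": 0.0, "fnr": 0.0, "n_true": 10,
                            "n_pred": 10, "n_missed": 0, "n_false": 0}
                        for e in ("SWP", "HC", "TO")}
            metrics.append(TrialMetrics(
                patient_id="P", trial_id=f"T{i}", leg="left", pearson=v,
                f1=v, f1_detail={}, per_type=per_type, cycle_stats=base))
        assert aggregate(metrics)["pearson_r"]["median"] == pytest.approx(0.85)

    def test_pooled_rates_use_pooled_counts(self):
        """Pooling must weight trials by event counts, not average rates."""
        def tm(n_true, n_missed, tid):
            per_type = {e: {"median_abs_displacement_ms": 0.0,
                            "iqr_low_ms": 0.0, "iqr_high_ms": 0.0,
                            "fdr": 0.0, "fnr": n_missed / n_true,
                            "n_true": n_true, "n_pred": n_true - n_missed,
                            "n_missed": n_missed, "n_false": 0}
                        for e in ("SWP", "HC", "TO")}
            return TrialMetrics(patient_id="P", trial_id=tid, leg="left",
                                pearson=0.9, f1=0.9, f1_detail={},
                                per_type=per_type, cycle_stats=None)
        s = aggregate([tm(100, 10, "a"), tm(10, 0, "b")])
        pooled = s["per_type"]["SWP"]["pooled_fnr"]
        assert pooled == pytest.approx(10 / 110)   # not (0.1 + 0.0) / 2
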