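import numpy as np
import pytest

from emg2gait import (CrossValidationError, DataError, LagGrid,
                      ModelMismatchError, MuscleSubset, ParameterError,
                      RegressionModel, embed, enumerate_subsets, fit_lopo,
                      fit_ols, predict)
from conftest import make_channel


def emg_set(rng, m, n, fs=200.0):
    sides = ("left", "right")
    return [make_channel(rng.standard_normal(n), fs=fs, kind="emg",
                         side=sides[i % 2], label=f"ch{i}")
            for i in range(m)]


class TestLagGrid:
    def test_default_grid_spans_one_second_in_21_steps(self):
        grid = LagGrid()
        assert grid.K == 21
        taus = grid.taus_ms()
        assert taus[0] == -500.0 and taus[-1] == 500.0
        np.testing.assert_allclose(np.diff(taus), 50.0)

    def test_lags_integer_in_samples_at_200hz(self):
        lags = LagGrid().lags_samples(200.0)
        np.testing.assert_array_equal(lags, np.arange(-100, 101, 10))

    def test_non_sample_aligned_grid_rejected(self):
        # 12 ms is not a whole number of samples at 200 Hz (5 ms/sample)
        with pytest.raises(ParameterError):
            LagGrid(tau_start_ms=-12.0, tau_end_ms=12.0,
                    step_ms=12.0).lags_samples(200.0)


class TestEmbed:
    def test_ten_muscles_yield_210_lagged_features(self, rng):
        design = embed(emg_set(rng, 10, 600), LagGrid())
        assert design.n_rows == 211            # 210 lagged + offset
        np.testing.assert_array_equal(design.features[-1], 1.0)

    def test_single_zero_lag_is_identity(self, rng):
        chans = emg_set(rng, 3, 100)
        grid = LagGrid(tau_start_ms=0.0, tau_end_ms=0.0, step_ms=50.0)
        design = embed(chans, grid)
        for m, ch in enumerate(chans):
            np.testing.assert_array_equal(design.features[m], ch.samples)

    def test_indexing_oracle(self, rng):
        """Row (m, k) at column t equals x_m[t + lag_k] wherever defined."""
        chans = emg_set(rng, 2, 500)
        grid = LagGrid()
        design = embed(chans, grid)
        lags = grid.lags_samples(200.0)
        T = 500
        for m, ch in enumerate(chans):
            for k, lag in enumerate(lags):
                row = design.features[m * grid.K + k]
                for t in (0, 99, 100, 250, 399, 400, 499):
                    if 0 <= t + lag < T:
                        assert row[t] == ch.samples[t + lag]
                    else:
                        assert np.isnan(row[t])

    def test_valid_mask_excludes_embedding_margins(self, rng):
        design = embed(emg_set(rng, 1, 500), LagGrid())
        expected = np.zeros(500, bool)
        expected[100:400] = True
        np.testing.assert_array_equal(design.valid, expected)

    def test_trial_shorter_than_span_rejected(self, rng):
        with pytest.raises(DataError):
            embed(emg_set(rng, 1, 150), LagGrid())


class TestFitOls:
    def test_construct_and_recover_noiseless(self, rng):
        design = embed(emg_set(rng, 2, 800), LagGrid())
        beta_true = rng.standard_normal(design.n_rows)
        y = beta_true @ np.nan_to_num(design.features)
        y[~design.valid] = np.nan
        model = fit_ols(design, np.where(design.valid, y, np.nan))
        np.testing.assert_allclose(model.beta, beta_true, atol=1e-6)
        resid = model.beta @ design.features[:, design.valid] - y[design.valid]
        assert np.mean(resid ** 2) / np.mean(y[design.valid] ** 2) < 1e-18

    def test_intercept_only_target(self, rng):
        design = embed(emg_set(rng, 1, 600), LagGrid())
        y = np.full(600, 4.2)
        model = fit_ols(design, y)
        assert abs(model.beta[-1] - 4.2) < 1e-6
        assert np.all(np.abs(model.beta[:-1]) < 1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        """SVD least squares equals the closed-form (X X^T)^-1 X y^T."""
        for _ in range(20):
            X = rng.standard_normal((20, 500))
            y = rng.standard_normal(500)
            beta_ne = np.linalg.solve(X @ X.T, X @ y)
            beta_ls, *_ = np.linalg.lstsq(X.T, y, rcond=None)
            np.testing.assert_allclose(beta_ls, beta_ne, rtol=1e-8, atol=1e-10)

    def test_too_few_valid_samples_rejected(self, rng):
        design = embed(emg_set(rng, 2, 220), LagGrid())
        with pytest.raises(DataError):
            fit_ols(design, np.zeros(220))


class TestPredict:
    def test_zero_design_predicts_intercept(self, rng):
        chans = [make_channel(np.zeros(500), fs=200.0, kind="emg",
                              label="LVl")]
        design = embed(chans, LagGrid())
        beta = np.zeros(design.n_rows)
        beta[-1] = 2.5
        model = RegressionModel(beta=beta, target_side="left",
                                muscle_labels=design.muscle_labels,
                                lag_grid=design.lag_grid)
        out = predict(model, design)
        np.testing.assert_allclose(out.samples[design.valid], 2.5)
        assert np.all(np.isnan(out.samples[~design.valid]))

    def test_one_hot_beta_reproduces_shifted_channel(self, rng):
        chans = emg_set(rng, 1, 500)
        grid = LagGrid()
        design = embed(chans, grid)
        k = 13  # lag of +150 ms = +30 samples
        beta = np.zeros(design.n_rows)
        beta[k] = 1.0
        model = RegressionModel(beta=beta, target_side="left",
                                muscle_labels=design.muscle_labels,
                                lag_grid=grid)
        out = predict(model, design)
        lag = grid.lags_samples(200.0)[k]
        valid = np.nonzero(design.valid)[0]
        np.testing.assert_array_equal(out.samples[valid],
                                      chans[0].samples[valid + lag])

    def test_training_fit_beats_single_features(self, rng):
        design = embed(emg_set(rng, 2, 1000), LagGrid())
        y = np.sin(np.arange(1000) / 20.0) + 0.1 * rng.standard_normal(1000)
        model = fit_ols(design, y)
        out = predict(model, design)
        v = design.valid
        r_model = np.corrcoef(out.samples[v], y[v])[0, 1]
        for row in design.features[:-1]:
            r_feat = abs(np.corrcoef(row[v], y[v])[0, 1])
            assert r_model >= r_feat - 1e-12

    def test_feature_mismatch_rejected(self, rng):
        design = embed(emg_set(rng, 2, 500), LagGrid())
        other = embed(emg_set(rng, 1, 500), LagGrid())
        model = fit_ols(design, rng.standard_normal(500))
        with pytest.raises(ModelMismatchError):
            predict(model, other)


class TestSubsets:
    def test_thirty_one_bilateral_subsets(self):
        subsets = enumerate_subsets()
        assert len(subsets) == 31
        assert len({s.pairs for s in subsets}) == 31
        assert sum(1 for s in subsets if len(s.pairs) == 1) == 5
        for s in subsets:
            nch = len(s.channels)
            assert nch == 2 * len(s.pairs)
            assert nch % 2 == 0 and 2 <= nch <= 10
            # bilateral: both sides of every pair
            for pair in s.pairs:
                assert f"L{pair}" in s.channels and f"R{pair}" in s.channels

    def test_invalid_subsets_rejected(self):
        with pytest.raises(ParameterError):
            MuscleSubset(pairs=())
        with pytest.raises(ParameterError):
            MuscleSubset(pairs=("Vl", "Vl"))
        with pytest.raises(ParameterError):
            MuscleSubset(pairs=("Quadriceps",))


class TestLopo:
    def test_each_patient_held_out_exactly_once(self, linear_lopo):
        prep, result = linear_lopo
        patients = {rec.patient_id for rec in prep}
        held_out = {p for (p, _side) in result.models}
        assert held_out == patients
        per_patient = {p: sum(1 for pr in result.predictions
                              if pr.patient_id == p) for p in patients}
        # 2 trials x 2 sides per held-out patient
        assert all(n == 4 for n in per_patient.values())

    def test_held_out_correlation_high_under_linear_truth(self, linear_lopo):
        from emg2gait import pearson_r
        _, result = linear_lopo
        rs = [pearson_r(p.measured, p.predicted) for p in result.predictions]
        assert np.median(rs) > 0.99

    def test_single_patient_rejected(self, linear_cohort):
        _, prep = linear_cohort
        alone = [r for r in prep if r.patient_id == prep[0].patient_id]
        with pytest.raises(CrossValidationError):
            fit_lopo(alone, MuscleSubset(pairs=("Vl",)))

    def test_no_leakage_from_held_out_imu(self, linear_cohort):
        """Arbitrarily modifying the held-out patient's angular-velocity
        traces leaves that fold's coefficients bit-identical."""
        from dataclasses import replace
        _, prep = linear_cohort
        held = prep[0].patient_id
        result = fit_lopo(prep, MuscleSubset(pairs=("Vl",)))

        perturbed = []
        for rec in prep:
            if rec.patient_id == held:
                channels = []
                for ch in rec.channels:
                    if ch.kind == "angular_velocity":
                        channels.append(ch.with_samples(
                            ch.samples[::-1] * 3.7 + 100.0))
                    else:
                        channels.append(ch)
                perturbed.append(replace(rec, channels=channels))
            else:
                perturbed.append(rec)
        result2 = fit_lopo(perturbed, MuscleSubset(pairs=("Vl",)))
        for side in ("left", "right"):
            np.testing.assert_array_equal(
                result.models[(held, side)].beta,
                result2.models[(held, side)].beta)

    def test_training_columns_never_straddle_trials(self, linear_cohort):
        """Concatenation keeps only per-trial valid columns, so the training
        column count equals the sum of per-trial valid counts."""
        _, prep = linear_cohort
        grid = LagGrid()
        subset = MuscleSubset(pairs=("Vl",))
        designs = [embed([rec.channel(c) for c in subset.channels], grid)
                   for rec in prep]
        for rec, design in zip(prep, designs):
            n = rec.channel("LVl").n
            assert design.valid.sum() == n - 200  # 100 samples per margin


def test_model_json_round_trip(tmp_path, rng):
    design = embed(emg_set(rng, 2, 500), LagGrid())
    model = fit_ols(design, rng.standard_normal(500), ["P01", "P02"])
    model.to_json(tmp_path / "m.json")
    back = RegressionModel.from_json(tmp_path / "m.json")
    np.testing.assert_array_equal(back.beta, model.beta)
    assert back.muscle_labels == model.muscle_labels
    assert back.lag_grid == model.lag_grid
    assert back.training_patients == ("P01", "P02")
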