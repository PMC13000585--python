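"""Z-scoring and the standardized multivariate linear model."""

import numpy as np
import pandas as pd
import pytest

from phenoxscreen.regression import (
    FEATURE_COLUMNS,
    fit_linear,
    predict,
    rank_candidates,
    zscore,
)


def _table(X, ids=None):
    df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
    if ids is not None:
        df["candidate_id"] = ids
    return df


def _planted(n, betas=(7.5, 1.4, -2.0, -1.1), noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3)) * [0.03, 0.2, 5.0] + [0.05, 0.5, 30.0]
    feats = zscore(_table(X))
    k = (betas[0] + feats.values @ np.array(betas[1:])
         + rng.normal(0, noise_sd, size=n))
    return feats, k


class TestZscore:
    def test_population_sd_hand_computation(self):
        feats = zscore(_table(np.column_stack([[1.0, 2.0, 3.0]] * 3)))
        expected = np.array([-1.2247448714, 0.0, 1.2247448714])
        assert np.allclose(feats.values[:, 0], expected)

    def test_columns_have_zero_mean_unit_sd(self, rng):
        feats = zscore(_table(rng.normal(size=(50, 3)) * [1, 10, 100]))
        assert np.allclose(feats.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(feats.values.std(axis=0), 1.0, atol=1e-10)

    def test_idempotent_on_standardized_input(self, rng):
        feats = zscore(_table(rng.normal(size=(30, 3))))
        again = zscore(_table(feats.values))
        assert np.allclose(again.values, feats.values, atol=1e-10)

    def test_inverse_round_trip(self, rng):
        X = rng.normal(size=(20, 3)) * [0.1, 1.0, 10.0]
        feats = zscore(_table(X))
        assert np.allclose(feats.inverse(), X, atol=1e-12)

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="p_HB"):
            zscore(_table(X))


class TestFitLinear:
    def test_noiseless_planted_model_recovered_exactly(self):
        feats, k = _planted(50, betas=(7.5, 1.4, -2.0, -1.1))
        model = fit_linear(feats, k)
        assert np.allclose(model.betas, [7.5, 1.4, -2.0, -1.1], atol=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_intercept_equals_mean_response(self, rng):
        feats, k = _planted(100, noise_sd=1.0, seed=3)
        model = fit_linear(feats, k)
        assert model.beta0 == pytest.approx(k.mean(), abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        feats, k = _planted(40, noise_sd=2.0, seed=4)
        model = fit_linear(feats, k)
        X = np.column_stack([np.ones(40), feats.values])
        beta_ne = np.linalg.solve(X.T @ X, X.T @ k)
        assert np.allclose(model.betas, beta_ne, atol=1e-9)

    def test_constant_response_r2_zero_with_warning(self):
        feats, _ = _planted(20)
        with pytest.warns(UserWarning, match="constant response"):
            model = fit_linear(feats, np.full(20, 4.0))
        assert model.r_squared == 0.0
        assert np.allclose(model.betas[1:], 0.0, atol=1e-10)

    def test_r2_invariant_under_affine_feature_rescaling(self, rng):
        X = rng.normal(size=(60, 3))
        k = 2.0 + X @ [1.0, -0.5, 0.3] + rng.normal(0, 0.5, 60)
        r2_a = fit_linear(zscore(_table(X)), k).r_squared
        r2_b = fit_linear(zscore(_table(X * [3.0, 0.01, 100.0] + 7.0)), k).r_squared
        assert r2_a == pytest.approx(r2_b, abs=1e-12)

    def test_sign_pattern_recovered_under_noise_at_full_scale(self):
        # noise sized for a planted R^2 near 0.65 at n = 718
        betas = (7.5, 1.4, -2.0, -1.1)
        signal_var = sum(b * b for b in betas[1:])
        noise_sd = np.sqrt(signal_var * 0.35 / 0.65)
        feats, k = _planted(718, betas=betas, noise_sd=noise_sd, seed=5)
        model = fit_linear(feats, k)
        se = noise_sd / np.sqrt(718)
        for est, true in zip(model.betas[1:], betas[1:]):
            assert abs(est - true) < 3 * se * 1.5
        assert np.sign(model.beta1) > 0
        assert np.sign(model.beta2) < 0 and np.sign(model.beta3) < 0
        assert 0.5 < model.r_squared < 0.8

    def test_bias_shrinks_with_sample_size(self):
        errs = []
        for n in (50, 200, 718):
            diffs = []
            for s in range(10):
                feats, k = _planted(n, noise_sd=2.0, seed=100 * n + s)
                model = fit_linear(feats, k)
                diffs.append(model.betas[1:] - [1.4, -2.0, -1.1])
            errs.append(np.abs(np.mean(diffs, axis=0)).max())
        assert errs[-1] < errs[0]

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0) * 2, np.ones(10)])
        X += np.random.default_rng(0).normal(0, 1e-14, X.shape)
        feats = zscore(_table(np.column_stack([X[:, 0], X[:, 0], X[:, 2] + np.arange(10)])))
        with pytest.raises(ValueError, match="rank-deficient|zero-variance"):
            fit_linear(feats, np.arange(10.0))


class TestPredict:
    def test_zero_row_gives_intercept(self):
        feats, k = _planted(30)
        model = fit_linear(feats, k)
        from phenoxscreen.regression import StandardizedFeatures

        zero = StandardizedFeatures(values=np.zeros((1, 3)), means=feats.means,
                                    sds=feats.sds)
        assert predict(model, zero)[0] == pytest.approx(model.beta0)

    def test_training_residuals_sum_to_zero(self, rng):
        feats, k = _planted(80, noise_sd=1.5, seed=8)
        model = fit_linear(feats, k)
        resid = k - predict(model, feats)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_predictions_equal_targets(self):
        feats, k = _planted(25)
        model = fit_linear(feats, k)
        assert np.allclose(predict(model, feats), k, atol=1e-8)

    def test_wrong_standardization_context_rejected(self, rng):
        feats, k = _planted(30)
        model = fit_linear(feats, k)
        other = zscore(_table(rng.normal(size=(30, 3))))
        with pytest.raises(ValueError, match="training means"):
            predict(model, other)


class TestRanking:
    def test_monotone_feature_map_preserves_stability_order(self):
        feats, k = _planted(40, seed=9)
        model = fit_linear(feats, k)
        ranked = rank_candidates(model, feats)
        khat = ranked["k_hat_ns_inv"].to_numpy()
        assert np.all(np.diff(khat) >= 0)
        # most stable first: lowest predicted rate constant at rank 1
        assert ranked.loc[0, "rank"] == 1
        assert khat[0] == khat.min()

    def test_sign_flip_reverses_ranking(self):
        feats, k = _planted(15, seed=10)
        model = fit_linear(feats, k)
        flipped = fit_linear(feats, -k)
        a = rank_candidates(model, feats)["candidate_id"].tolist()
        b = rank_candidates(flipped, feats)["candidate_id"].tolist()
        assert a == b[::-1]

    def test_ties_break_on_candidate_id(self):
        from phenoxscreen.regression import LinearModel, StandardizedFeatures

        feats = StandardizedFeatures(values=np.zeros((4, 3)),
                                     means=np.zeros(3), sds=np.ones(3),
                                     candidate_ids=np.array([9, 3, 7, 1]))
        model = LinearModel(beta0=5.0, beta1=0.0, beta2=0.0, beta3=0.0,
                            r_squared=0.0, n=4, feature_means=np.zeros(3),
                            feature_sds=np.ones(3))
        ranked = rank_candidates(model, feats)
        assert ranked["candidate_id"].tolist() == [1, 3, 7, 9]
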