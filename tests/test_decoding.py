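"""Lag designs, ridge decoders, reconstruction accuracy, tracking index."""

import dataclasses

import numpy as np

import pytest
from scipy.sparse.linalg import lsqr
from scipy.stats import pearsonr

from dichotic.config import DecodingConfig, SimulationConfig
from dichotic.decoding import (
    Decoder,
    build_lag_design,
    decode_dataset,
    forward_transform,
    select_lambda,
    sliding_correlation,
    tracking_index,
    train_decoder,
    validate_decoder_specificity,
    _RidgeSet,
)
from dichotic.synthetic import generate_dataset


def _ridge_oracle(R, s, lam):
    """Independent iterative solver: LSQR on the centered augmented system."""
    Rc = R - R.mean(axis=0)
    sc = s - s.mean()
    m = np.trace(Rc.T @ Rc) / Rc.shape[1]
    return lsqr(Rc, sc, damp=np.sqrt(lam * m), atol=1e-14, btol=1e-14,
                iter_lim=100000)[0]


class TestLagDesign:
    def test_single_parcel_zero_lag_is_identity(self):
        r = np.random.default_rng(0).normal(size=50)
        X = build_lag_design(r, np.array([0]))
        assert np.array_equal(X[:, 0], r)

    def test_shift_convention_against_oracle(self):
        r = np.zeros(20)
        k = 7
        r[k] = 1.0
        X = build_lag_design(r, np.array([0, 1]))
        # column for lag +1 holds r[t+1]: the impulse appears at t = k-1
        oracle = np.zeros(20)
        oracle[k - 1] = 1.0
        assert np.array_equal(X[:, 1], oracle)
        assert np.array_equal(X[:, 0], r)

    def test_default_grid_gives_760_columns(self):
        cfg = DecodingConfig()
        assert len(cfg.lags) == 76
        r = np.zeros((30, 10))
        assert build_lag_design(r, cfg.lags).shape == (30, 760)


class TestRidge:
    def test_matches_iterative_oracle(self):
        rng = np.random.default_rng(1)
        lags = np.array([0])
        for _ in range(20):
            n = rng.integers(20, 51)
            p = rng.integers(2, 6)
            R1 = rng.normal(size=(n, p))
            R2 = rng.normal(size=(n, p))
            s1, s2 = rng.normal(size=n), rng.normal(size=n)
            lam = 10.0 ** rng.integers(-3, 3)
            dec = train_decoder([R1, R2], [s1, s2], lam,
                                lags=np.arange(p), n_parcels=1, pad=0)
            R = np.vstack([R1, R2])
            s = np.concatenate([s1, s2])
            oracle = _ridge_oracle(R, s, lam)
            assert np.max(np.abs(dec.weights - oracle)) < 1e-8

    def test_huge_lambda_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(2)
        R1, R2 = rng.normal(size=(2, 40, 3))
        s1, s2 = rng.normal(size=(2, 40))
        dec = train_decoder([R1, R2], [s1, s2], 1e10,
                            lags=np.arange(3), n_parcels=1, pad=0)
        assert np.linalg.norm(dec.weights) < 1e-8

    def test_weight_norm_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        R1, R2 = rng.normal(size=(2, 60, 4))
        s1, s2 = rng.normal(size=(2, 60))
        norms = []
        for lam in DecodingConfig().lambda_grid:
            dec = train_decoder([R1, R2], [s1, s2], lam,
                                lags=np.arange(4), n_parcels=1, pad=0)
            norms.append(np.linalg.norm(dec.weights))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_generative_recovery(self):
        rng = np.random.default_rng(4)
        g_true = rng.normal(size=6)
        R1, R2 = rng.normal(size=(2, 400, 6))
        s1, s2 = R1 @ g_true, R2 @ g_true
        dec = train_decoder([R1, R2], [s1, s2], 1e-5,
                            lags=np.arange(6), n_parcels=1, pad=0)
        assert np.max(np.abs(dec.weights - g_true)) < 1e-3

    def test_needs_two_trials(self):
        with pytest.raises(ValueError, match="two"):
            train_decoder([np.zeros((10, 2))], [np.zeros(10)], 1.0,
                          lags=np.arange(2), n_parcels=1)


class TestLambdaSelection:
    def test_degenerate_grid_returns_value(self):
        rng = np.random.default_rng(5)
        designs = [rng.normal(size=(200, 4)) for _ in range(4)]
        envs = [rng.normal(size=200) for _ in range(4)]
        rs = _RidgeSet(designs, envs, envs, pad=0)
        assert select_lambda([rs], [7.0], window=31) == 7.0

    def test_pure_noise_terminates_finite(self):
        rng = np.random.default_rng(6)
        designs = [rng.normal(size=(200, 4)) for _ in range(4)]
        envs = [rng.normal(size=200) for _ in range(4)]
        rs = _RidgeSet(designs, envs, envs, pad=0)
        lam = select_lambda([rs], DecodingConfig().lambda_grid, window=31)
        assert np.isfinite(lam) and lam in DecodingConfig().lambda_grid

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        g_true = rng.normal(size=4)
        designs = [rng.normal(size=(150, 4)) for _ in range(5)]
        envs = [X @ g_true + 0.5 * rng.normal(size=150) for X in designs]
        rs = _RidgeSet(designs, envs, envs, pad=0)
        grid = [1e-4, 1e-2, 1.0, 1e2, 1e4]
        lam = select_lambda([rs], grid, window=31, n_folds=5)

        # oracle: independent brute-force cross-validation via train_decoder
        best, best_r = None, -np.inf
        for cand in grid:
            rs_scores = []
            for f in range(5):
                fold = list(range(5))[f::5]
                train = [i for i in range(5) if i not in fold]
                dec = train_decoder([designs[i] for i in train],
                                    [envs[i] for i in train], cand,
                                    lags=np.arange(4), n_parcels=1, pad=0)
                for i in fold:
                    pred = dec.predict(designs[i])
                    r = sliding_correlation(pred, envs[i], 31)
                    rs_scores.append(np.nanmean(r))
            mean_r = np.mean(rs_scores)
            if mean_r > best_r:
                best, best_r = cand, mean_r
        assert lam == best


class TestSlidingCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        r = sliding_correlation(x, x, 31)
        assert np.allclose(r[15:-15], 1.0)
        assert np.isnan(r[:15]).all() and np.isnan(r[-15:]).all()

    def test_negated_correlation_is_minus_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        assert np.allclose(sliding_correlation(x, -x, 31)[15:-15], -1.0)

    def test_one_window_matches_pearson_formula(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(2, 80))
        r = sliding_correlation(x, y, 31)
        k = 40
        direct = pearsonr(x[k - 15:k + 16], y[k - 15:k + 16]).statistic
        assert abs(r[k] - direct) < 1e-12

    def test_zero_variance_window_is_missing(self):
        x = np.zeros(100)
        y = np.random.default_rng(11).normal(size=100)
        assert np.isnan(sliding_correlation(x, y, 31)).all()


class TestTrackingIndex:
    def test_equal_inputs_give_zero(self):
        x = np.array([0.5, 0.2, 0.9])
        assert np.allclose(tracking_index(x, x), 0.0)

    def test_hand_computed_value(self):
        assert tracking_index(np.array([0.6]), np.array([0.2]))[0] == pytest.approx(0.5)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(12)
        a, b = rng.uniform(0.1, 0.9, size=(2, 50))
        assert np.allclose(tracking_index(a, b), -tracking_index(b, a))

    def test_near_zero_denominator_is_missing(self):
        out = tracking_index(np.array([0.5, 1e-8]), np.array([0.2, -1e-8]))
        assert out[0] == pytest.approx(0.3 / 0.7)
        assert np.isnan(out[1])

    def test_missing_propagates(self):
        out = tracking_index(np.array([np.nan, 0.4]), np.array([0.2, 0.2]))
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestForwardTransform:
    @staticmethod
    def _decoder(w, lags, n_parcels):
        return Decoder(weights=w, lags=lags, n_parcels=n_parcels,
                       lam=1.0, m=1.0)

    def test_identity_covariance_returns_backward(self):
        w = np.arange(6, dtype=float)
        d = self._decoder(w, np.arange(3), 2)
        fw = forward_transform(d, np.eye(6), 1.0)
        assert np.allclose(fw, d.weight_matrix)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(13)
        w = rng.normal(size=6)
        cov = rng.normal(size=(6, 6))
        cov = cov @ cov.T
        d = self._decoder(w, np.arange(3), 2)
        fw1 = forward_transform(d, cov, 2.0)
        fw2 = forward_transform(d, 4.0 * cov, 8.0)
        assert np.allclose(fw1, fw2)


class TestLeaveOneOut:
    def test_two_trials_each_decoded_by_the_other(self):
        rng = np.random.default_rng(14)
        designs = [rng.normal(size=(120, 4)) for _ in range(2)]
        envs = [rng.normal(size=120) for _ in range(2)]
        rs = _RidgeSet(designs, envs, envs, pad=0)
        sol_excl0 = rs.solve(1.0, exclude=[0])["attended"]
        # oracle: closed form on trial 1 alone
        R = designs[1]
        s = envs[1]
        Rc = R - R.mean(axis=0)
        sc = s - s.mean()
        G = Rc.T @ Rc
        m = np.trace(G) / G.shape[0]
        w_oracle = np.linalg.solve(G + 1.0 * m * np.eye(4), Rc.T @ sc)
        assert np.allclose(sol_excl0[0], w_oracle, atol=1e-10)

    def test_including_own_trial_overfits(self):
        """Training on a trial's own data inflates its reconstruction."""
        rng = np.random.default_rng(15)
        g_true = rng.normal(size=4)
        designs = [rng.normal(size=(150, 4)) for _ in range(6)]
        envs = [X @ g_true + 2.0 * rng.normal(size=150) for X in designs]
        rs = _RidgeSet(designs, envs, envs, pad=0)
        diffs = []
        for i in range(6):
            w_in, cm_in, sm_in, _ = rs.solve(1.0)["attended"]
            w_out, cm_out, sm_out, _ = rs.solve(1.0, exclude=[i])["attended"]
            X = designs[i]
            r_in = np.nanmean(sliding_correlation((X - cm_in) @ w_in + sm_in,
                                                  envs[i], 31))
            r_out = np.nanmean(sliding_correlation((X - cm_out) @ w_out + sm_out,
                                                   envs[i], 31))
            diffs.append(r_in - r_out)
        assert np.mean(diffs) > 0


class TestDatasetDecoding:
    def test_divided_trials_use_probed_side_decoders(self, small_dataset):
        """A probed-right divided trial must be decoded with the full
        attend-right decoders (trained on all selective attend-right trials)."""
        ds = small_dataset
        res = decode_dataset(ds, DecodingConfig(), lam=1.0)
        trials = ds.trials
        row = trials[(trials["spatial_cue"] == "uninformative")
                     & (trials["probed_ear"] == "right")].iloc[0]
        i = row.name
        from dichotic.decoding import _prepare_responses
        cfg = DecodingConfig()
        responses = _prepare_responses(ds, cfg)
        s0, s1 = int(row["sentence_start"]), int(row["sentence_end"])
        X = build_lag_design(responses[i].T, cfg.lags)[s0:s1]
        d = res.per_subject[row["subject"]].decoders[("right", "attended")]
        pred = d.predict(X)
        r_series = sliding_correlation(
            pred, ds.envelopes["right"][i, s0:s1], cfg.window_samples)
        expected = res.table[(res.table["trial"] == row["trial"])]["r_att_mean"].iloc[0]
        assert np.nanmean(r_series) == pytest.approx(expected, abs=1e-12)

    def test_label_swap_flips_tracking_index_sign(self, small_dataset):
        """Relabelling attended/ignored envelopes flips the per-trial index."""
        ds = small_dataset
        res = decode_dataset(ds, DecodingConfig(), lam=1.0)
        swapped = dataclasses.replace(
            ds, envelopes={"left": ds.envelopes["right"],
                           "right": ds.envelopes["left"]})
        res_sw = decode_dataset(swapped, DecodingConfig(), lam=1.0)
        a = res.table.set_index("trial")["nti_sentence"]
        b = res_sw.table.set_index("trial")["nti_sentence"]
        assert np.allclose(a, -b, atol=1e-9, equal_nan=True)

    def test_subject_with_too_few_trials_skipped(self, caplog):
        cfg = SimulationConfig(n_subjects=1, n_trials_per_cell=1, seed=33)
        ds = generate_dataset(cfg)
        import logging
        with caplog.at_level(logging.WARNING):
            res = decode_dataset(ds, DecodingConfig(), lam=1.0)
        assert "skipped" in caplog.text
        # with one trial per cell, only one probed ear has >= 2 selective
        # trials; every decoded trial must belong to that ear
        decoded = set(res.table["trial"])
        ears = ds.trials.set_index("trial").loc[sorted(decoded), "probed_ear"]
        assert ears.nunique() == 1

    def test_specificity_contrast_positive_with_unequal_gains(self, small_dataset):
        res = decode_dataset(small_dataset, DecodingConfig(), lam=1.0)
        spec = validate_decoder_specificity(small_dataset, res)
        assert (spec["contrast"] > 0).all()
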