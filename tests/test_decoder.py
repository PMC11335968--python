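"""Backward mTRF decoding: preprocessing, lag design, ridge training,
lambda selection, leave-one-out evaluation and forward projection."""

import numpy as np
import pytest
from scipy import signal

import speechtrack as st
from speechtrack.decoder import _pearson


def white_block(n_channels=4, n=2048, fs=256.0, seed=0):
    rng = np.random.default_rng(seed)
    return st.EEGBlock(rng.standard_normal((n_channels, n)), fs)


class TestPreprocess:
    def test_high_frequencies_attenuated(self):
        out = st.preprocess_block(white_block(n=65536))
        f, pxx = signal.welch(out.data[0], 32.0, nperseg=256)
        pass_band = pxx[(f > 1) & (f < 5)].mean()
        # forward-backward first-order Butterworth has power gain |H|^4:
        # above 12 Hz that is under 10% of the passband
        stop_band = pxx[f >= 12].mean()
        assert stop_band < 0.1 * pass_band
        # and the measured roll-off tracks the analytic response
        sel = (f > 0.5) & (f < 15)
        analytic = 1.0 / (1.0 + (f[sel] / 8.0) ** 2) ** 2
        measured = pxx[sel] / pxx[(f > 0.5) & (f < 2)].mean()
        assert np.corrcoef(measured, analytic)[0, 1] > 0.95

    def test_constant_channel_flagged_and_zeroed(self):
        blk = white_block()
        blk.data[2] = 5.0
        out = st.preprocess_block(blk)
        assert out.channel_labels[2] in out.flagged_channels
        assert np.all(out.data[2] == 0.0)

    def test_normalization_contract(self):
        out = st.preprocess_block(white_block())
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.data.std(axis=1), 1.0, atol=1e-10)
        assert out.fs == 32.0


class TestLagMatrix:
    def test_single_channel_zero_lag_is_identity(self):
        blk = st.EEGBlock(np.arange(10.0)[None, :], 32.0)
        X = st.build_lag_matrix(blk, lag_min_ms=0.0, lag_max_ms=0.0)
        np.testing.assert_array_equal(X[:, 0], np.arange(10.0))

    def test_matches_brute_force_indexing_oracle(self):
        # 2 channels, lags {-1, 0, 1} at fs=1000 with a 1 ms grid
        data = np.arange(10.0).reshape(2, 5)
        blk = st.EEGBlock(data, 1000.0)
        X = st.build_lag_matrix(blk, lag_min_ms=-1.0, lag_max_ms=1.0)
        lags = [-1, 0, 1]
        expected = np.zeros((5, 6))
        for t in range(5):
            for ch in range(2):
                for j, L in enumerate(lags):
                    if 0 <= t + L < 5:
                        expected[t, ch * 3 + j] = data[ch, t + L]
        np.testing.assert_array_equal(X, expected)

    def test_boundary_rows_zero_padded(self):
        blk = white_block(2, 64, 32.0)
        X = st.build_lag_matrix(blk)
        n_lags = st.lag_samples(32.0).size
        neg = np.where(st.lag_samples(32.0) < 0)[0]
        first_row = X[0].reshape(2, n_lags)
        assert np.all(first_row[:, neg] == 0.0)

    def test_lag_count_convention(self):
        assert st.lag_samples(32.0).size == 33  # -250..750 ms at 32 Hz

    def test_lag_span_too_long_rejected(self):
        blk = white_block(1, 20, 32.0)
        with pytest.raises(st.InvalidWindowError):
            st.build_lag_matrix(blk)


class TestRidge:
    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 8))
        s = rng.standard_normal(50)
        lam = 2.5
        model = st.train_decoder(X, s, lam)
        Xc = X - X.mean(axis=0)
        w_oracle = np.linalg.inv(Xc.T @ Xc + lam * np.eye(8)) @ Xc.T @ (s - s.mean())
        np.testing.assert_allclose(model.flat_weights, w_oracle, atol=1e-8)

    def test_extreme_shrinkage_kills_weights(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 6))
        s = rng.standard_normal(200)
        model = st.train_decoder(X, s, 1e12)
        assert np.linalg.norm(model.flat_weights) < 1e-8

    def test_representable_target_fits_tightly(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((300, 5))
        s = X[:, 2].copy()
        model = st.train_decoder(X, s, 1e-3)
        assert _pearson(model.predict(X), s) > 0.999

    def test_shrinkage_monotonicity(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 10))
        s = rng.standard_normal(100)
        norms = [
            np.linalg.norm(st.train_decoder(X, s, lam).flat_weights)
            for lam in st.LAMBDA_GRID
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_non_finite_inputs_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            st.train_decoder(X, np.ones(10), 1.0)


class TestLambdaSelection:
    @staticmethod
    def _blocks(seed=8, n_blocks=4, n=400, p=12, noise=1.0):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(p)
        out = []
        for _ in range(n_blocks):
            X = rng.standard_normal((n, p))
            s = X @ w + noise * rng.standard_normal(n)
            out.append((X, s))
        return out

    def test_matches_exhaustive_grid_oracle(self):
        blocks = self._blocks()
        chosen = st.select_lambda(blocks)
        # oracle: independently evaluate every grid value with the public
        # training routine, rotating the validation block
        mean_r = []
        for lam in st.LAMBDA_GRID:
            rs = []
            for v in range(len(blocks)):
                train = [b for i, b in enumerate(blocks) if i != v]
                Xt = np.vstack([X for X, _ in train])
                str_ = np.concatenate([s for _, s in train])
                model = st.train_decoder(Xt, str_, lam)
                rs.append(_pearson(model.predict(blocks[v][0]), blocks[v][1]))
            mean_r.append(np.mean(rs))
        best = max(mean_r)
        chosen_r = mean_r[st.LAMBDA_GRID.index(chosen)]
        assert chosen_r >= best - 0.02 * abs(best)

    def test_grid_of_one_returns_it(self):
        assert st.select_lambda(self._blocks(n_blocks=2), grid=[7.0]) == 7.0

    def test_single_block_rejected(self):
        with pytest.raises(st.InsufficientFoldsError):
            st.select_lambda(self._blocks(n_blocks=1))

    def test_pure_noise_still_returns_grid_member(self):
        rng = np.random.default_rng(9)
        blocks = [
            (rng.standard_normal((300, 6)), rng.standard_normal(300))
            for _ in range(3)
        ]
        assert st.select_lambda(blocks) in st.LAMBDA_GRID


class TestLeaveOneOut:
    @staticmethod
    def _subject(noise_sd, seed, n_blocks=4, n_channels=8, dur=60.0):
        truth = st.make_default_truth(
            n_channels=n_channels, noise_sd=noise_sd, seed=seed
        )
        blocks = st.simulate_subject(
            truth, n_blocks=n_blocks, block_duration_s=dur,
            n_channels=n_channels, seed=seed + 1,
        )
        return blocks

    def test_fold_bookkeeping(self):
        blocks = self._subject(2.0, 20, n_blocks=4, dur=30.0)
        res = st.decode_leave_one_out(
            [b.eeg for b in blocks], [b.target_stims["delta_env"] for b in blocks]
        )
        tested = [f["test"] for f in res.folds]
        assert sorted(tested) == [0, 1, 2, 3]
        for f in res.folds:
            assert f["test"] not in f["train"]
            assert len(f["train"]) == 3

    def test_independent_stimulus_gives_null_correlations(self):
        # stimulus drawn independently of the EEG: held-out r centered at 0
        rs = []
        for subj in range(12):
            blocks = self._subject(1.0, 100 + subj, n_blocks=3, n_channels=4, dur=30.0)
            other = st.simulate_subject(
                st.make_default_truth(n_channels=4, noise_sd=1.0, seed=900 + subj),
                n_blocks=3, block_duration_s=30.0, n_channels=4, seed=990 + subj,
            )
            res = st.decode_leave_one_out(
                [b.eeg for b in blocks],
                [o.target_stims["delta_env"] for o in other],
            )
            rs.append(res.r.mean())
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 2 * se + 0.02

    def test_pearson_invariant_to_stimulus_rescaling(self):
        blocks = self._subject(2.0, 30, n_blocks=3, dur=30.0)
        stims = [b.target_stims["delta_env"].values for b in blocks]
        eegs = [b.eeg for b in blocks]
        r1 = st.decode_leave_one_out(eegs, stims).r
        r2 = st.decode_leave_one_out(eegs, [3.0 * s + 1.0 for s in stims]).r
        np.testing.assert_allclose(r1, r2, atol=1e-9)

    def test_no_leakage_into_held_out_block(self):
        blocks = self._subject(1.0, 40, n_blocks=4, dur=60.0)
        eegs = [b.eeg for b in blocks]
        stims = [b.target_stims["delta_env"].values for b in blocks]
        res = st.decode_leave_one_out(eegs, stims)
        # shuffling the held-out stimulus destroys its r but cannot change
        # its own reconstruction (the held-out stimulus never enters the
        # training fold that produces it)
        rng = np.random.default_rng(0)
        shuffled = stims[0][rng.permutation(stims[0].size)]
        res2 = st.decode_leave_one_out(eegs, [shuffled] + stims[1:])
        np.testing.assert_allclose(
            res.reconstructions[0], res2.reconstructions[0], atol=1e-9
        )
        assert res.r[0] > 0.3 and abs(res2.r[0]) < 0.1

    def test_too_few_blocks_rejected(self):
        blocks = self._subject(1.0, 50, n_blocks=3, dur=30.0)
        with pytest.raises(st.InsufficientFoldsError):
            st.decode_leave_one_out(
                [b.eeg for b in blocks[:2]],
                [b.target_stims["delta_env"] for b in blocks[:2]],
            )


class TestForwardProjection:
    def test_scalar_case_proportional_to_backward_weight(self):
        rng = np.random.default_rng(60)
        X = rng.standard_normal((500, 1))
        model = st.DecoderModel(np.array([[0.7]]), lam=1.0, intercept=0.0)
        recon = (X @ model.flat_weights)
        fwd = st.forward_project(model, X, recon)
        expected = np.var(X[:, 0], ddof=1) * 0.7 / np.var(recon, ddof=1)
        assert fwd.coefficients[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_decorrelated_channels_pattern_matches_weights(self):
        rng = np.random.default_rng(61)
        X = rng.standard_normal((20000, 3))
        w = np.array([0.5, -1.0, 2.0])
        model = st.DecoderModel(w.reshape(3, 1), lam=1.0, intercept=0.0)
        recon = X @ w
        fwd = st.forward_project(model, X, recon)
        pat = fwd.coefficients.ravel()
        np.testing.assert_allclose(pat / pat[0], w / w[0], rtol=0.05)

    def test_correlated_two_channel_toy_matches_hand_computation(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        rng = np.random.default_rng(62)
        X = rng.multivariate_normal([0, 0], cov, size=4000)
        w = np.array([1.0, -0.5])
        recon = X @ w
        model = st.DecoderModel(w.reshape(2, 1), lam=1.0, intercept=0.0)
        fwd = st.forward_project(model, X, recon)
        Xc = X - X.mean(axis=0)
        cov_hat = Xc.T @ Xc / (X.shape[0] - 1)
        expected = cov_hat @ w / np.var(recon, ddof=1)
        np.testing.assert_allclose(fwd.coefficients.ravel(), expected, atol=1e-8)

    def test_zero_variance_reconstruction_rejected(self):
        model = st.DecoderModel(np.ones((2, 1)), lam=1.0, intercept=0.0)
        with pytest.raises(st.DegenerateProjectionError):
            st.forward_project(model, np.random.default_rng(0).standard_normal((50, 2)),
                               np.zeros(50))

    def test_kernel_shape_recovered_on_synthetic_data(self):
        # forward pattern of a decoder trained on low-noise forward-model
        # data driven by a *white* stimulus resembles the generating
        # kernel (a colored stimulus would smear the pattern by its
        # autocorrelation)
        rng = np.random.default_rng(70)
        truth = st.make_default_truth(n_channels=6, noise_sd=0.1, seed=70)
        n = 32 * 120
        s = st.StimulusFunction(rng.standard_normal(n), 32.0, "delta_env")
        eeg = st.generate_eeg({"delta_env": s}, None, truth, n_channels=6, seed=71)
        X = st.build_lag_matrix(eeg)
        model = st.train_decoder(X, s.values, 1.0, n_channels=6)
        fwd = st.forward_project(model, X, model.predict(X))
        k, a = truth.trf_delta.ravel(), fwd.coefficients.ravel()
        cos = abs(k @ a) / (np.linalg.norm(k) * np.linalg.norm(a))
        assert cos > 0.9
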