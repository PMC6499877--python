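"""Denoising autoencoder, softmax head, LORO, and permutation machinery."""

import dataclasses

import numpy as np
import pytest

import prfdecode as pfd
from prfdecode.autoencoder import (
    _ae_loss_grads,
    _train_heads_batched,
    classifier_config,
    init_autoencoder,
    labels_to_indices,
    predict_letters,
)


class TestCorrupt:
    def test_zero_sd_is_identity(self):
        y = np.arange(10.0)
        assert np.array_equal(pfd.corrupt(y, 0.0, 1), y)

    def test_noise_moments(self):
        y = np.zeros(2000)
        eps = pfd.corrupt(y, 12.0, 2) - y
        # sample variance within 3 SE of sd^2 at v = 2000
        se = 12.0**2 * np.sqrt(2.0 / (2000 - 1))
        assert abs(eps.var(ddof=1) - 144.0) < 3 * se
        assert abs(eps.mean()) < 3 * 12.0 / np.sqrt(2000)

    def test_seed_reproducible_and_negative_sd_rejected(self):
        y = np.ones(50)
        assert np.array_equal(pfd.corrupt(y, 2.0, 7), pfd.corrupt(y, 2.0, 7))
        with pytest.raises(ValueError):
            pfd.corrupt(y, -1.0, 0)


class TestForward:
    def test_zero_parameters_restore_zero(self):
        p = pfd.AutoencoderParams(
            W_e=np.zeros((3, 12)), b_e=np.zeros(3), b_d=np.zeros(12)
        )
        h, yr = pfd.ae_forward(p, np.random.default_rng(0).normal(size=12))
        assert np.allclose(h, 0) and np.allclose(yr, 0)

    def test_identity_construction_under_rectifier(self):
        # k = v, W_e = I: nonnegative inputs pass through unchanged
        p = pfd.AutoencoderParams(
            W_e=np.eye(6), b_e=np.zeros(6), b_d=np.zeros(6)
        )
        y = np.abs(np.random.default_rng(1).normal(size=6))
        _, yr = pfd.ae_forward(p, y)
        assert np.allclose(yr, y)

    def test_length_mismatch_rejected(self):
        p = init_autoencoder(20, seed=0)
        with pytest.raises(ValueError, match="length"):
            pfd.ae_forward(p, np.zeros(19))

    @pytest.mark.parametrize("activation", ["relu", "logistic"])
    def test_gradients_match_finite_differences(self, activation):
        rng = np.random.default_rng(2)
        p = init_autoencoder(10, activation=activation, seed=3)
        p.W_e = rng.normal(0, 0.3, p.W_e.shape)  # k = 1 for v = 10
        p.b_e = rng.normal(0, 0.3, p.b_e.shape)
        p.b_d = rng.normal(0, 0.3, p.b_d.shape)
        Y = rng.normal(size=(4, 10))
        Yc = Y + rng.normal(0, 0.5, Y.shape)
        _, grads = _ae_loss_grads(p, Yc, Y)
        eps = 1e-6
        for arr, g in zip((p.W_e, p.b_e, p.b_d), grads):
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                arr[ix] += eps
                lp, _ = _ae_loss_grads(p, Yc, Y)
                arr[ix] -= 2 * eps
                lm, _ = _ae_loss_grads(p, Yc, Y)
                arr[ix] += eps
                num[ix] = (lp - lm) / (2 * eps)
            denom = max(np.abs(num).max(), 1e-12)
            assert np.abs(num - g).max() / denom <= 1e-5


class TestTrainAutoencoder:
    def test_hidden_size_rule(self):
        assert pfd.hidden_size(2000) == 200
        assert pfd.hidden_size(399) == 39
        assert pfd.hidden_size(5) == 1

    def test_training_denoises_and_attracts(self, perceptual_averages, trained_ae):
        ae = trained_ae
        rng = np.random.default_rng(4)
        for y in perceptual_averages:
            # restoration of the clean attractor itself
            assert np.corrcoef(pfd.denoise(ae, y), y)[0, 1] > 0.95
            # denoising beats the corrupted input (20 corruption draws)
            mse_in, mse_out = [], []
            for _ in range(20):
                yc = pfd.corrupt(y, 12.0, rng)
                mse_in.append(np.mean((yc - y) ** 2))
                mse_out.append(np.mean((pfd.denoise(ae, yc) - y) ** 2))
            assert np.mean(mse_out) < np.mean(mse_in)

    def test_zero_attractor_shrinks_pure_noise(self, trained_ae):
        rng = np.random.default_rng(5)
        noise = rng.normal(size=trained_ae.v)
        restored = pfd.denoise(trained_ae, noise)
        assert np.linalg.norm(restored) < 0.5 * np.linalg.norm(noise)

    def test_deterministic_under_seed(self, perceptual_averages):
        cfg = dataclasses.replace(pfd.autoencoder_config(seed=6), iterations=50)
        a = pfd.train_autoencoder(perceptual_averages, cfg)
        b = pfd.train_autoencoder(perceptual_averages, cfg)
        assert np.array_equal(a.W_e, b.W_e)

    def test_untrained_params_cannot_denoise(self):
        p = init_autoencoder(30, seed=7)
        with pytest.raises(ValueError, match="trained"):
            pfd.denoise(p, np.zeros(30))

    def test_wrong_training_set_shape_rejected(self):
        with pytest.raises(ValueError, match="4"):
            pfd.train_autoencoder(np.zeros((3, 10)))


class TestClassifierHead:
    def test_separable_hidden_reps_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(8)
        v = 40
        templates = rng.normal(size=(4, v)) * 3
        X = np.repeat(templates, 24, axis=0) + rng.normal(0, 0.1, (96, v))
        labels = [pfd.LETTERS[i // 24] for i in range(96)]
        ae = pfd.train_autoencoder(
            (templates - templates.mean(1, keepdims=True))
            / templates.std(1, keepdims=True),
            pfd.autoencoder_config(seed=9),
        )
        head = pfd.train_classifier_head(ae, X, labels)
        assert (np.array(predict_letters(head, ae, X)) == labels).mean() == 1.0

    def test_encoder_frozen_bitwise(self, trained_ae, small_patterns):
        im = small_patterns.subset(condition="imagery")
        before = (trained_ae.W_e.copy(), trained_ae.b_e.copy())
        pfd.train_classifier_head(
            trained_ae, im.values[:32], im.manifest.letter[:32].tolist(),
            dataclasses.replace(classifier_config(), iterations=20),
        )
        assert np.array_equal(trained_ae.W_e, before[0])
        assert np.array_equal(trained_ae.b_e, before[1])

    def test_loss_decreases_on_default_schedule(self, trained_ae, small_patterns):
        im = small_patterns.subset(condition="imagery")
        head = pfd.train_classifier_head(
            trained_ae, im.values, im.manifest.letter.tolist()
        )
        smooth = np.convolve(head.loss_history, np.ones(25) / 25, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_missing_class_rejected(self, trained_ae, small_patterns):
        im = small_patterns.subset(condition="imagery", letter="H")
        with pytest.raises(ValueError, match="missing"):
            pfd.train_classifier_head(
                trained_ae, im.values, im.manifest.letter.tolist()
            )


class TestLoro:
    def test_fold_bookkeeping_96_32(self, small_patterns, trained_ae):
        res = pfd.loro_cross_validate(small_patterns, trained_ae)
        assert res.train_sizes == [96] * 4
        assert res.test_sizes == [32] * 4
        assert len(res.fold_accuracies) == 4

    def test_accuracies_match_recount_oracle(self, small_patterns, trained_ae):
        cfg = classifier_config()
        res = pfd.loro_cross_validate(small_patterns, trained_ae, cfg)
        im = small_patterns.subset(condition="imagery")
        run_ids = im.manifest.run.to_numpy()
        labels = labels_to_indices(im.manifest.letter.tolist())
        for held, acc in zip(res.fold_runs, res.fold_accuracies):
            tr = run_ids != held
            head = pfd.train_classifier_head(
                trained_ae, im.values[tr],
                [pfd.LETTERS[i] for i in labels[tr]], cfg,
            )
            pred = predict_letters(head, trained_ae, im.values[~tr])
            manual = np.mean(
                [pfd.LETTERS.index(p) == t for p, t in zip(pred, labels[~tr])]
            )
            assert acc == pytest.approx(manual)

    def test_unbalanced_runs_rejected(self, small_patterns, trained_ae):
        im = small_patterns.subset(condition="imagery")
        broken = pfd.PatternSet(
            values=im.values[:-1], manifest=im.manifest[:-1]
        )
        with pytest.raises(ValueError, match="balanced"):
            pfd.loro_cross_validate(broken, trained_ae)


class TestPermutation:
    def test_nearest_rank_percentile_definition(self):
        vals = np.arange(1, 101, dtype=float)
        assert pfd.nearest_rank_percentile(vals, 95.0) == 95.0
        assert pfd.nearest_rank_percentile(np.array([3.0, 1.0, 2.0]), 50.0) == 2.0

    def test_batched_training_equals_sequential(self, trained_ae, small_patterns):
        im = small_patterns.subset(condition="imagery")
        cfg = classifier_config(seed=0)
        labels = labels_to_indices(im.manifest.letter.tolist())[:96]
        head = pfd.train_classifier_head(
            trained_ae, im.values[:96], [pfd.LETTERS[i] for i in labels], cfg
        )
        H = pfd.hidden_representation(trained_ae, im.values[:96])
        W, b = _train_heads_batched(H, labels[None, :], cfg)
        assert np.allclose(W[0], head.W_c, atol=1e-12)
        assert np.allclose(b[0, 0], head.b_c, atol=1e-12)

    def test_small_permutation_count_warns(self, small_patterns, trained_ae):
        with pytest.warns(UserWarning, match="unstable"):
            res = pfd.permutation_test(
                small_patterns, trained_ae, n_permutations=50, seed=1
            )
        assert res.null.shape == (50,)
        assert ((res.null >= 0) & (res.null <= 1)).all()
        assert res.threshold == pfd.nearest_rank_percentile(res.null, 95.0)
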