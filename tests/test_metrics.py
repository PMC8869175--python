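"""Metric oracles: closed forms, independent reference implementations and
identity optima for the generative-image evaluation suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogan import metrics
from cytogan.metrics import (GaussianMoments, PairedBatch, PixelBackbone,
                             fid, gaussian_moments, inception_score, l1_l2,
                             mse_psnr, pair_images, prf, ssim,
                             perceptual_distance)


def random_probs(rng, n, k):
    p = rng.uniform(0.01, 1.0, (n, k))
    return p / p.sum(axis=1, keepdims=True)


class TestInceptionScore:
    def test_rows_equal_to_marginal_score_one(self):
        p = np.tile([[0.2, 0.3, 0.5]], (30, 1))
        mean, sd = inception_score(p)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_one_hot_covering_k_classes_scores_k(self):
        K = 12
        p = np.tile(np.eye(K), (10, 1))
        mean, sd = inception_score(p)
        assert mean == pytest.approx(K, rel=1e-6)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        p = random_probs(rng, 40, 5)
        mean, _ = inception_score(p, n_splits=1)
        marginal = p.mean(axis=0)
        kl = np.sum(p * (np.log(p) - np.log(marginal)), axis=1)
        assert mean == pytest.approx(np.exp(kl.mean()), abs=1e-8)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            inception_score(np.array([[0.5, 0.6]]))

    @given(st.integers(2, 6), st.integers(10, 40), st.integers(0, 5))
    @settings(max_examples=25, deadline=None)
    def test_bounded_between_one_and_k_and_row_order_invariant(
            self, k, n, seed):
        rng = np.random.default_rng(seed)
        p = random_probs(rng, n, k)
        mean, _ = inception_score(p, n_splits=1)
        assert 1.0 - 1e-9 <= mean <= k + 1e-9
        perm = rng.permutation(n)
        mean_p, _ = inception_score(p[perm], n_splits=1)
        assert mean == pytest.approx(mean_p, rel=1e-9)


class TestGaussianMoments:
    def test_identical_rows_zero_covariance(self):
        m = gaussian_moments(np.tile([1.0, 2.0], (5, 1)))
        assert np.allclose(m.sigma, 0.0)

    def test_1d_maximum_likelihood_convention(self):
        m = gaussian_moments(np.array([[0.0], [2.0]]))
        assert m.mu[0] == pytest.approx(1.0)
        assert m.sigma[0, 0] == pytest.approx(1.0)  # ML: divide by N

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(10, 3))
        a = gaussian_moments(f)
        b = gaussian_moments(f[rng.permutation(10)])
        assert np.allclose(a.mu, b.mu) and np.allclose(a.sigma, b.sigma)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            gaussian_moments(np.ones((1, 3)))


def random_psd(rng, d):
    a = rng.normal(size=(d, d))
    return a @ a.T + 0.1 * np.eye(d)


class TestFID:
    def test_identical_moments_give_zero(self):
        rng = np.random.default_rng(0)
        m = GaussianMoments(rng.normal(size=4), random_psd(rng, 4))
        assert fid(m, m) == pytest.approx(0.0, abs=1e-8)

    def test_1d_closed_form(self):
        a = GaussianMoments(np.array([0.0]), np.array([[1.0]]))
        b = GaussianMoments(np.array([3.0]), np.array([[1.0]]))
        assert fid(a, b) == pytest.approx(9.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        a = GaussianMoments(rng.normal(size=5), random_psd(rng, 5))
        b = GaussianMoments(rng.normal(size=5), random_psd(rng, 5))

        # oracle: trace term via sqrt(Sa)^T Sb sqrt(Sa) eigen square root
        wa, va = np.linalg.eigh(a.sigma)
        sqrt_a = va @ np.diag(np.sqrt(np.clip(wa, 0, None))) @ va.T
        inner = sqrt_a @ b.sigma @ sqrt_a
        wi = np.clip(np.linalg.eigvalsh(inner), 0, None)
        oracle = (np.sum((a.mu - b.mu) ** 2) + np.trace(a.sigma)
                  + np.trace(b.sigma) - 2 * np.sum(np.sqrt(wi)))
        assert fid(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fid(GaussianMoments(np.zeros(2), np.eye(2)),
                GaussianMoments(np.zeros(3), np.eye(3)))

    @given(st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a = GaussianMoments(rng.normal(size=3), random_psd(rng, 3))
        b = GaussianMoments(rng.normal(size=3), random_psd(rng, 3))
        ab, ba = fid(a, b), fid(b, a)
        assert ab >= 0.0
        assert ab == pytest.approx(ba, rel=1e-6, abs=1e-8)


class TestPairedErrors:
    def test_identical_pairs_are_optimal_everywhere(self):
        rng = np.random.default_rng(0)
        imgs = rng.uniform(0, 1, (4, 16, 16, 3))
        pairs = PairedBatch(real=imgs, synthetic=imgs.copy())
        assert l1_l2(pairs) == (0.0, 0.0)
        mse, psnr = mse_psnr(pairs, R=1.0)
        assert mse == 0.0 and psnr == float("inf")
        assert ssim(pairs, R=1.0) == pytest.approx(1.0, abs=1e-9)
        assert perceptual_distance(pairs, PixelBackbone()) == pytest.approx(
            0.0, abs=1e-12)

    def test_l1_l2_hand_computation(self):
        pairs = PairedBatch(real=np.array([[1.0, 2.0, 3.0]]),
                            synthetic=np.array([[0.0, 2.0, 5.0]]))
        l1, l2 = l1_l2(pairs)
        assert (l1, l2) == (3.0, 5.0)

    def test_l2_bounded_by_l1_times_max_diff(self):
        rng = np.random.default_rng(1)
        pairs = PairedBatch(real=rng.normal(size=(3, 10)),
                            synthetic=rng.normal(size=(3, 10)))
        l1, l2 = l1_l2(pairs)
        assert l2 <= l1 * np.abs(pairs.real - pairs.synthetic).max() + 1e-12

    def test_psnr_closed_form_unit_difference(self):
        real = np.zeros((1, 8, 8))
        synth = np.ones((1, 8, 8))
        mse, psnr = mse_psnr(PairedBatch(real=real, synthetic=synth), R=255.0)
        assert mse == pytest.approx(1.0)
        assert psnr == pytest.approx(10 * np.log10(255.0 ** 2), abs=1e-9)
        assert psnr == pytest.approx(48.13, abs=0.01)

    def test_doubling_error_lowers_psnr_6db(self):
        rng = np.random.default_rng(2)
        real = rng.uniform(0, 100, (2, 8, 8))
        d = rng.uniform(0, 10, (2, 8, 8))
        _, p1 = mse_psnr(PairedBatch(real=real, synthetic=real + d), R=255)
        _, p2 = mse_psnr(PairedBatch(real=real, synthetic=real + 2 * d),
                         R=255)
        assert p1 - p2 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_nonpositive_dynamic_range_rejected(self):
        pairs = PairedBatch(real=np.zeros((1, 4, 4)),
                            synthetic=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            mse_psnr(pairs, R=0.0)


class TestSSIM:
    def test_constant_images_reduce_to_luminance_term(self):
        a, b, R = 30.0, 80.0, 255.0
        C1 = (0.01 * R) ** 2
        pairs = PairedBatch(real=np.full((1, 16, 16), a),
                            synthetic=np.full((1, 16, 16), b))
        expected = (2 * a * b + C1) / (a * a + b * b + C1)
        assert ssim(pairs, R=R) == pytest.approx(expected, rel=1e-9)

    def test_matches_reference_implementation(self):
        from skimage.metrics import structural_similarity as sk_ssim

        rng = np.random.default_rng(3)
        x = rng.uniform(0, 255, (32, 32))
        y = np.clip(x + rng.normal(0, 20, (32, 32)), 0, 255)
        ours = metrics.structural_similarity(x, y, window=7, R=255.0)
        ref = sk_ssim(x, y, win_size=7, data_range=255.0,
                      gaussian_weights=False)
        assert ours == pytest.approx(ref, abs=1e-4)

    def test_window_larger_than_image_rejected(self):
        pairs = PairedBatch(real=np.zeros((1, 4, 4)),
                            synthetic=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            ssim(pairs, window=9)


class TestPerceptualDistance:
    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (3, 16, 16, 3))
        b = rng.uniform(0, 1, (3, 16, 16, 3))
        bb = PixelBackbone()
        d1 = perceptual_distance(PairedBatch(real=a, synthetic=b), bb)
        d2 = perceptual_distance(PairedBatch(real=b, synthetic=a), bb)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_monotone_under_growing_noise(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.7, (4, 16, 16, 3))
        bb = PixelBackbone()
        medians = []
        for amp in (0.02, 0.1, 0.4):
            vals = []
            for t in range(20):
                noisy = base + rng.normal(0, amp, base.shape)
                vals.append(perceptual_distance(
                    PairedBatch(real=base, synthetic=noisy), bb))
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]


@pytest.fixture(scope="module")
def manifests(tmp_path_factory):
    from cytogan.fixtures import FixtureSpec, generate_fixture_dataset

    root = tmp_path_factory.mktemp("pairing")
    spec = FixtureSpec(n_classes=2, per_class_counts=[8, 8],
                       image_size=16, seed=4)
    manifest = generate_fixture_dataset(spec, root)
    return root, manifest


class TestPairImages:

    def test_duplicated_manifest_pairs_with_itself(self, manifests):
        root, manifest = manifests
        pairs = pair_images(manifest, manifest, seed=0, real_root=root,
                            synth_root=root)
        l1, _ = l1_l2(pairs)
        assert l1 == 0.0

    def test_deterministic_given_seed(self, manifests):
        root, manifest = manifests
        a = pair_images(manifest, manifest, strategy="random-within-class",
                        seed=5, real_root=root, synth_root=root)
        b = pair_images(manifest, manifest, strategy="random-within-class",
                        seed=5, real_root=root, synth_root=root)
        assert np.array_equal(a.real, b.real)

    def test_nn_pairing_never_worse_than_random(self, manifests):
        root, manifest = manifests
        nn = pair_images(manifest, manifest, strategy="nn-within-class",
                         seed=0, real_root=root, synth_root=root)
        l2_nn = l1_l2(nn)[1]
        l2_rand = []
        for seed in range(20):
            rnd = pair_images(manifest, manifest,
                              strategy="random-within-class", seed=seed,
                              real_root=root, synth_root=root)
            l2_rand.append(l1_l2(rnd)[1])
        assert l2_nn <= np.median(l2_rand)

    def test_class_missing_from_real_rejected(self, manifests):
        root, manifest = manifests
        from cytogan.dataset import DatasetManifest

        first_class = manifest.labels()[0]
        real_only_one = DatasetManifest(
            r for r in manifest.records if r.label == first_class)
        with pytest.raises(ValueError):
            pair_images(real_only_one, manifest, seed=0, real_root=root,
                        synth_root=root)


class TestPRF:
    def test_diagonal_confusion_is_perfect(self):
        out = prf(np.diag([5, 3, 7]))
        assert out["precision"] == out["recall"] == out["f1"] == 1.0
        assert all(s == 1.0 for s in out["per_class"]["specificity"])

    def test_two_class_hand_computation(self):
        out = prf(np.array([[8, 2], [1, 9]]))
        per = out["per_class"]
        assert per["precision"][0] == pytest.approx(8 / 9)
        assert per["recall"][0] == pytest.approx(8 / 10)
        assert per["specificity"][0] == pytest.approx(9 / 10)

    def test_matches_sklearn_macro_scores(self):
        from sklearn.metrics import (confusion_matrix, precision_score,
                                     recall_score)

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 200)
        y_pred = np.where(rng.uniform(size=200) < 0.7, y_true,
                          rng.integers(0, 4, 200))
        cm = confusion_matrix(y_true, y_pred)
        out = prf(cm)
        assert out["precision"] == pytest.approx(
            precision_score(y_true, y_pred, average="macro"), abs=1e-12)
        assert out["recall"] == pytest.approx(
            recall_score(y_true, y_pred, average="macro"), abs=1e-12)

    def test_label_permutation_permutes_per_class_outputs(self):
        cm = np.array([[8, 2, 0], [1, 9, 3], [2, 0, 5]])
        perm = [2, 0, 1]
        out = prf(cm)
        out_p = prf(cm[np.ix_(perm, perm)])
        for key in ("precision", "recall", "specificity", "accuracy"):
            reordered = [out["per_class"][key][i] for i in perm]
            assert out_p["per_class"][key] == pytest.approx(reordered)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            prf(np.zeros((3, 3)))
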