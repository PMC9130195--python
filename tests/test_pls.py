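import numpy as np
import pytest

from chronopls.core import SampleMeta
from chronopls.pls import (
    ClassEncoding,
    hca_ward,
    nipals_fit,
    pca_svd,
    plsda_assign,
    plsda_encode,
    predict,
    vip_scores,
)


def _random_xy(seed, n=20, p=10, m=1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + 0.1 * rng.normal(size=(n, m))
    return X, (Y[:, 0] if m == 1 else Y)


class TestNIPALS:
    def test_exact_univariate_relation(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        m = nipals_fit(X, y, A=1)
        np.testing.assert_allclose(predict(m, X)[:, 0], y, atol=1e-12)
        # coefficient on the original scale reproduces the slope
        assert m.B[0, 0] / m.x_scale[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_equals_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 15, 6
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        m = nipals_fit(X, y, A=p)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        np.testing.assert_allclose(predict(m, X)[:, 0], Xc @ beta + y.mean(), atol=1e-8)

    @pytest.mark.parametrize("m_resp", [1, 3])
    def test_score_orthogonality(self, m_resp):
        X, Y = _random_xy(3, n=20, p=10, m=m_resp)
        model = nipals_fit(X, Y, A=5)
        gram = model.T.T @ model.T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention(self):
        X, y = _random_xy(4)
        model = nipals_fit(X, y, A=3)
        for a in range(3):
            w = model.W[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_explained_x_variance_bounded(self):
        X, y = _random_xy(5)
        model = nipals_fit(X, y, A=6, scale=True)
        assert np.all(model.explained_x_variance >= -1e-12)
        assert model.explained_x_variance.sum() <= 1 + 1e-8

    def test_invalid_inputs(self):
        X, y = _random_xy(6, n=10, p=4)
        with pytest.raises(ValueError, match="outside"):
            nipals_fit(X, y, A=10)
        with pytest.raises(ValueError, match="zero-variance response"):
            nipals_fit(X, np.ones(10), A=1)

    def test_sklearn_cross_check(self):
        """Fitted values match the independent scikit-learn PLS solver."""
        from sklearn.cross_decomposition import PLSRegression

        for seed in range(5):
            X, y = _random_xy(seed, n=20, p=8)
            for a in (1, 2, 4):
                ours = predict(nipals_fit(X, y, A=a, scale=True), X)[:, 0]
                ref = np.ravel(
                    PLSRegression(n_components=a, scale=True, tol=1e-12).fit(X, y).predict(X)
                )
                np.testing.assert_allclose(ours, ref, atol=1e-6)


class TestPredict:
    def test_training_reproduction_and_mean_identity(self):
        X, y = _random_xy(7)
        m = nipals_fit(X, y, A=3)
        np.testing.assert_allclose(predict(m, X), predict(m, X))
        # a sample at the column means predicts the response mean
        np.testing.assert_allclose(
            predict(m, X.mean(axis=0))[0, 0], y.mean(), atol=1e-10
        )

    def test_dimension_mismatch(self):
        X, y = _random_xy(8)
        m = nipals_fit(X, y, A=2)
        with pytest.raises(ValueError, match="columns"):
            predict(m, X[:, :3])


class TestVIP:
    def test_single_variable_is_one(self):
        X = np.array([[1.0], [2.0], [4.0], [3.0]])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        m = nipals_fit(X, y, A=1)
        np.testing.assert_allclose(vip_scores(m), [1.0])

    def test_duplicated_column_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        X = np.column_stack([x, x])
        y = 2 * x + 0.01 * rng.normal(size=12)
        m = nipals_fit(X, y, A=1)
        v = vip_scores(m)
        np.testing.assert_allclose(v, [1.0, 1.0], atol=1e-10)

    @pytest.mark.parametrize("seed,p", [(0, 8), (1, 8), (2, 5)])
    def test_normalization_sums_to_p(self, seed, p):
        X, y = _random_xy(seed, n=20, p=p)
        m = nipals_fit(X, y, A=3)
        assert (vip_scores(m) ** 2).sum() == pytest.approx(p, abs=1e-8)

    def test_brute_force_formula(self):
        """VIP agrees with a literal evaluation of its defining formula."""
        X, Y = _random_xy(10, n=20, p=8, m=2)
        m = nipals_fit(X, Y, A=3)
        p = X.shape[1]
        ssy = m.ssy
        expected = np.array(
            [
                np.sqrt(
                    p
                    * sum(
                        ssy[a] * (m.W[j, a] / np.linalg.norm(m.W[:, a])) ** 2
                        for a in range(3)
                    )
                    / ssy.sum()
                )
                for j in range(p)
            ]
        )
        np.testing.assert_allclose(vip_scores(m), expected, atol=1e-10)
        # per-class VIPs also normalize to p
        for k in range(2):
            vk = vip_scores(m, response_column=k)
            assert (vk ** 2).sum() == pytest.approx(p, abs=1e-8)


class TestClassEncoding:
    def _samples(self, days):
        return [SampleMeta(f"B{d}_r{i}", "B", d, 1 + i % 3) for i, d in enumerate(days)]

    def test_merged_class_has_four_columns(self):
        enc = plsda_encode(self._samples([1, 4, 8, 12, 16]), merges=((8, 12),))
        assert enc.classes == ["1", "4", "8/12", "16"]
        assert enc.Y.shape == (5, 4)
        np.testing.assert_array_equal(enc.Y.sum(axis=1), 1.0)
        assert enc.day_to_class[8] == enc.day_to_class[12] == "8/12"

    def test_no_merges_gives_five_columns(self):
        enc = plsda_encode(self._samples([1, 4, 8, 12, 16]))
        assert enc.Y.shape == (5, 5)

    def test_day_outside_design_rejected(self):
        with pytest.raises(ValueError, match="outside design days"):
            plsda_encode(self._samples([1, 3]), allowed_days=(1, 4, 8, 12, 16))

    def test_assignment_and_ties(self):
        enc = ClassEncoding.from_days([1, 4, 8, 16], merges=())
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 6))
        m = nipals_fit(X, enc.Y, A=3)
        labels, ties = plsda_assign(m, X, enc)
        assert labels == enc.labels  # training data, well separated
        # argmax tie-break toward the first class in encoding order
        scores = np.array([[0.5, 0.5, 0.0, 0.0]])
        assert int(np.argmax(scores[0])) == 0


class TestPCAHCA:
    def test_rank_one_explains_everything(self):
        u = np.linspace(-1, 1, 8)[:, None]
        v = np.array([[1.0, 2.0, 3.0]])
        X = u @ v
        scores, loadings, ev = pca_svd(X)
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 6))
        scores, loadings, ev = pca_svd(X)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings.T, Xc, atol=1e-8)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_autoscaled_variance_convention(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 5))
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        _, _, ev = pca_svd(Xs)
        # autoscaled columns each have unit variance -> total p
        assert ev.sum() == pytest.approx(5.0, abs=1e-10)

    def test_identical_samples_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z = hca_ward(X)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_two_blob_top_split(self):
        rng = np.random.default_rng(13)
        blob1 = rng.normal(0, 0.1, size=(6, 3))
        blob2 = rng.normal(5, 0.1, size=(6, 3))
        Z = hca_ward(np.vstack([blob1, blob2]))
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)  # monotone merges
        # the last merge joins the two blobs: its height dwarfs the rest
        assert heights[-1] > 10 * heights[-2]
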