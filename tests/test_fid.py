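"""Fréchet-distance evaluation: summaries, closed forms, invariances."""

import numpy as np
import pytest

from chestdiff import (
    Domain,
    GaussianSummary,
    ImageBatch,
    PhantomParams,
    ProjectionPoolExtractor,
    fid,
    fid_table,
    frechet_distance,
    generate_phantoms,
    summarize,
)
from chestdiff.fid import ShiftedExtractor


def gaussian_summary_1d(mu, var):
    return GaussianSummary(mu=np.array([mu]), sigma=np.array([[var]]), n=100)


class TestSummarize:
    def test_identical_rows_give_zero_covariance(self):
        f = np.tile([1.0, 2.0, 3.0], (5, 1))
        s = summarize(f)
        np.testing.assert_array_equal(s.sigma, np.zeros((3, 3)))
        np.testing.assert_array_equal(s.mu, [1.0, 2.0, 3.0])

    def test_two_point_closed_form(self):
        s = summarize(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_array_equal(s.mu, [1.0, 1.0])
        np.testing.assert_array_equal(s.sigma, [[2.0, 2.0], [2.0, 2.0]])

    def test_matches_double_loop_covariance_oracle(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((100, 5))
        s = summarize(f)
        mu = f.mean(axis=0)
        oracle = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                oracle[i, j] = np.sum((f[:, i] - mu[i]) * (f[:, j] - mu[j])) / 99
        assert np.max(np.abs(s.sigma - oracle)) < 1e-10

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2"):
            summarize(np.ones((1, 4)))


class TestFrechetDistance:
    def test_identical_summaries_give_zero(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((50, 6))
        a = summarize(f)
        assert frechet_distance(a, a) == pytest.approx(0.0, abs=1e-8)

    def test_1d_gaussian_closed_form(self):
        # (mu_a - mu_b)^2 + (sigma_a - sigma_b)^2
        a = gaussian_summary_1d(0.0, 1.0)
        b = gaussian_summary_1d(1.0, 1.0)
        assert frechet_distance(a, b) == pytest.approx(1.0, abs=1e-10)
        c = gaussian_summary_1d(0.5, 4.0)
        expected = 0.5**2 + (2.0 - 1.0) ** 2
        assert frechet_distance(gaussian_summary_1d(0.0, 1.0), c) == pytest.approx(
            expected, abs=1e-10
        )

    def test_commuting_spd_pairs_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        d = 8
        q, _ = np.linalg.qr(rng.standard_normal((d, d)))
        la = rng.uniform(0.5, 3.0, d)
        lb = rng.uniform(0.5, 3.0, d)
        sa = (q * la) @ q.T
        sb = (q * lb) @ q.T
        mu_a, mu_b = rng.standard_normal(d), rng.standard_normal(d)
        a = GaussianSummary(mu=mu_a, sigma=(sa + sa.T) / 2, n=10)
        b = GaussianSummary(mu=mu_b, sigma=(sb + sb.T) / 2, n=10)
        # shared eigenvectors: trace term reduces to sum (sqrt(la)-sqrt(lb))^2
        oracle = np.sum((mu_a - mu_b) ** 2) + np.sum((np.sqrt(la) - np.sqrt(lb)) ** 2)
        assert frechet_distance(a, b) == pytest.approx(oracle, rel=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = summarize(rng.standard_normal((40, 5)))
        b = summarize(rng.standard_normal((40, 5)) * 2 + 1)
        assert frechet_distance(a, b) == pytest.approx(frechet_distance(b, a), abs=1e-8)

    def test_scale_coherence(self):
        rng = np.random.default_rng(4)
        fa = rng.standard_normal((60, 4))
        fb = rng.standard_normal((60, 4)) + 0.5
        base = frechet_distance(summarize(fa), summarize(fb))
        c = 3.0
        scaled = frechet_distance(summarize(c * fa), summarize(c * fb))
        assert scaled == pytest.approx(c**2 * base, rel=1e-6)

    def test_dimension_mismatch_rejected(self):
        a = summarize(np.random.default_rng(0).standard_normal((10, 3)))
        b = summarize(np.random.default_rng(0).standard_normal((10, 4)))
        with pytest.raises(ValueError, match="dimension"):
            frechet_distance(a, b)

    def test_asymmetric_sigma_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            GaussianSummary(mu=np.zeros(2), sigma=np.array([[1.0, 0.5], [0.0, 1.0]]), n=5)


class TestProjectionPoolExtractor:
    def test_deterministic_and_dim_correct(self, phantoms64):
        for dim in (64, 16):
            ext = ProjectionPoolExtractor(dim=dim)
            f1, f2 = ext(phantoms64), ext(phantoms64)
            assert f1.shape == (64, dim)
            np.testing.assert_array_equal(f1, f2)

    def test_orthonormal_columns_at_small_dim(self):
        ext = ProjectionPoolExtractor(dim=64)
        gram = ext._w.T @ ext._w
        np.testing.assert_allclose(gram, np.eye(64), atol=1e-10)

    def test_orthonormal_rows_above_pixel_count(self):
        ext = ProjectionPoolExtractor(dim=2048)
        gram = ext._w @ ext._w.T
        np.testing.assert_allclose(gram, np.eye(784), atol=1e-10)

    def test_domain_invariance(self, phantoms64):
        from chestdiff import normalize

        ext = ProjectionPoolExtractor(dim=32)
        np.testing.assert_allclose(
            ext(phantoms64), ext(normalize(phantoms64)), atol=1e-5
        )


class TestFid:
    def test_self_identity(self, phantoms64):
        assert fid(phantoms64, phantoms64, ProjectionPoolExtractor(dim=64)) < 1e-3

    def test_mean_shift_gives_squared_norm(self, phantoms64):
        base = ProjectionPoolExtractor(dim=16)
        v = np.linspace(0.1, 0.4, 16)
        shifted = ShiftedExtractor(base, v)
        # same images, features shifted by v: distance = ||v||^2
        a = summarize(base(phantoms64))
        b = summarize(shifted(phantoms64))
        assert frechet_distance(a, b) == pytest.approx(np.sum(v**2), rel=1e-6)

    def test_distinct_distributions_strictly_positive_both_dims(self, phantoms64):
        noise = ImageBatch(
            np.random.default_rng(0).integers(0, 256, (64, 1, 28, 28)).astype(np.uint8),
            Domain.UINT8,
        )
        for dim in (64, 2048):
            assert fid(phantoms64, noise, ProjectionPoolExtractor(dim=dim)) > 1.0

    def test_too_few_images_rejected(self, phantoms64):
        one = ImageBatch(phantoms64.pixels[:1], Domain.UINT8)
        with pytest.raises(ValueError, match="2 images"):
            fid(phantoms64, one, ProjectionPoolExtractor(dim=8))


class TestFidTable:
    def test_layout_and_identity_values(self, phantoms64):
        more = generate_phantoms(PhantomParams(n=64, seed=13))
        extractors = [ProjectionPoolExtractor(dim=64), ProjectionPoolExtractor(dim=16)]
        table = fid_table(
            phantoms64,
            {"l1": phantoms64, "l2": more, "huber": phantoms64},
            extractors,
        )
        assert table.shape == (3, 2)
        assert list(table.columns) == ["64", "16"]
        assert list(table.index) == ["l1", "l2", "huber"]
        assert table.loc["l1", "64"] == pytest.approx(0.0, abs=1e-3)
        assert table.loc["l2", "64"] > 0

    def test_values_invariant_to_evaluation_order(self, phantoms64):
        more = generate_phantoms(PhantomParams(n=64, seed=13))
        exts = [ProjectionPoolExtractor(dim=16), ProjectionPoolExtractor(dim=8)]
        t1 = fid_table(phantoms64, {"a": more, "b": phantoms64}, exts)
        t2 = fid_table(phantoms64, {"b": phantoms64, "a": more}, list(reversed(exts)))
        for loss in ("a", "b"):
            for dim in ("16", "8"):
                assert t1.loc[loss, dim] == t2.loc[loss, dim]

    def test_empty_inputs_rejected(self, phantoms64):
        with pytest.raises(ValueError):
            fid_table(phantoms64, {}, [ProjectionPoolExtractor(dim=8)])
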