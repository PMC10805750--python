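"""t-SNE correctness against brute-force formula transcription; KDE and DO laws."""

import numpy as np
import pytest

from ecg2ppg import overlap as ov
from ecg2ppg import preprocess as pp


def _brute_affinities(x, sigma):
    """Direct transcription of the conditional/joint affinity formulas."""
    n = x.shape[0]
    d = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    cond = np.zeros((n, n))
    for i in range(n):
        w = np.exp(-d[i] / (2 * sigma[i] ** 2))
        w[i] = 0.0
        cond[i] = w / w.sum()
    return (cond + cond.T) / (2 * n)


class TestAffinities:
    def test_joint_probabilities_sum_to_one(self, rng):
        aff = ov.compute_affinities(rng.normal(size=(30, 6)), perplexity=10)
        assert abs(aff.p.sum() - 1.0) < 1e-10
        assert np.allclose(aff.p, aff.p.T)
        assert np.all(np.diag(aff.p) == 0)

    def test_equilateral_triangle_symmetric(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2],
                        [10, 10], [11, 10], [10.5, 10 + np.sqrt(3) / 2]])
        aff = ov.compute_affinities(pts, perplexity=2)
        tri = aff.p[:3, :3]
        off = tri[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0])

    def test_matches_brute_force_at_fitted_sigma(self, rng):
        x = rng.normal(size=(10, 3))
        aff = ov.compute_affinities(x, perplexity=6)
        assert np.abs(aff.p - _brute_affinities(x, aff.sigma)).max() < 1e-12

    def test_perplexity_matched_within_tolerance(self, rng):
        x = rng.normal(size=(40, 5))
        aff = ov.compute_affinities(x, perplexity=12, tol=1e-4)
        d = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        for i in range(40):
            w = np.exp(-d[i] / (2 * aff.sigma[i] ** 2))
            w[i] = 0
            p = w / w.sum()
            h = -np.sum(p[p > 0] * np.log(p[p > 0]))
            assert abs(np.exp(h) - 12) < 12 * 1e-3

    def test_duplicate_points_allowed(self):
        x = np.vstack([np.zeros((3, 2)), np.ones((4, 2))])
        aff = ov.compute_affinities(x, perplexity=3)
        assert np.isfinite(aff.p).all()

    def test_perplexity_at_least_n_rejected(self, rng):
        with pytest.raises(ValueError):
            ov.compute_affinities(rng.normal(size=(8, 2)), perplexity=8)


class TestGradientAndDescent:
    def test_analytic_gradient_matches_numeric(self, rng):
        x = rng.normal(size=(8, 4))
        aff = ov.compute_affinities(x, perplexity=4)
        y = rng.normal(size=(8, 2))
        grad = ov.kl_gradient(aff.p, y)
        num = np.zeros_like(y)
        eps = 1e-6
        for i in range(8):
            for j in range(2):
                yp, ym = y.copy(), y.copy()
                yp[i, j] += eps
                ym[i, j] -= eps
                num[i, j] = (ov.kl_cost(aff.p, yp) - ov.kl_cost(aff.p, ym)) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-5

    def test_kl_nonnegative_every_iteration(self, rng):
        emb = ov.tsne_embed(rng.normal(size=(40, 8)), perplexity=10, iters=200, seed=3)
        assert np.all(emb.kl_history >= 0)
        assert np.all(np.isfinite(emb.kl_history))

    def test_kl_nonincreasing_after_burn_in(self, rng):
        emb = ov.tsne_embed(rng.normal(size=(40, 8)), perplexity=10, iters=300, seed=4)
        assert np.all(np.diff(emb.kl_history[-50:]) <= 1e-7)

    def test_separated_clusters_remain_separable(self, rng):
        x = np.vstack([rng.normal(size=(50, 50)),
                       rng.normal(size=(50, 50)) + 20.0])
        emb = ov.tsne_embed(x, perplexity=15, iters=300, seed=5)
        y1, y2 = emb.y[:50], emb.y[50:]
        between = np.linalg.norm(y1.mean(0) - y2.mean(0))
        within = max(y1.std(), y2.std())
        assert between / within > 2.0

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(20, 4))
        a = ov.tsne_embed(x, perplexity=6, iters=100, seed=9)
        b = ov.tsne_embed(x, perplexity=6, iters=100, seed=9)
        assert np.array_equal(a.y, b.y)


class TestKDE:
    def test_cell_masses_sum_to_one(self, rng):
        y = rng.normal(size=(300, 2))
        h = ov.silverman_bandwidth(y)
        masses = ov.kde2d(y, ov.make_grid(y, h), h)
        assert abs(masses.sum() - 1.0) < 1e-9

    def test_tight_cluster_peaks_at_centroid(self, rng):
        y = rng.normal(scale=0.01, size=(50, 2)) + [3.0, -2.0]
        grid = ov.OverlapGrid(0.0, 6.0, -4.0, 0.0, resolution=60)
        masses = ov.kde2d(y, grid, bandwidth=0.05)
        a, b = np.unravel_index(np.argmax(masses), masses.shape)
        cx, cy = grid.centers()
        assert abs(cx[a] - 3.0) < 0.2 and abs(cy[b] + 2.0) < 0.2

    def test_standard_normal_matches_analytic_cell_integrals(self, rng):
        from scipy.stats import norm
        y = rng.standard_normal((10000, 2))
        h = ov.silverman_bandwidth(y)
        grid = ov.make_grid(y, h, resolution=50)
        masses = ov.kde2d(y, grid, h)
        cx, _ = grid.centers()
        dx = cx[1] - cx[0]
        ex = np.diff(norm.cdf(np.concatenate([cx - dx / 2, [cx[-1] + dx / 2]])))
        cy_ = grid.centers()[1]
        dy = cy_[1] - cy_[0]
        ey = np.diff(norm.cdf(np.concatenate([cy_ - dy / 2, [cy_[-1] + dy / 2]])))
        expect = np.outer(ex, ey) / (np.outer(ex, ey).sum())
        assert np.abs(masses - expect).max() < 0.005

    def test_degenerate_cloud_warns(self):
        y = np.zeros((10, 2))
        grid = ov.OverlapGrid(-1, 1, -1, 1, resolution=20)
        with pytest.warns(UserWarning):
            masses = ov.kde2d(y, grid, bandwidth=0.01)
        assert abs(masses.sum() - 1.0) < 1e-9


class TestDegreeOfOverlap:
    def test_identical_distributions_give_one(self, rng):
        y = rng.normal(size=(100, 2))
        h = ov.silverman_bandwidth(y)
        p = ov.kde2d(y, ov.make_grid(y, h), h)
        assert ov.degree_of_overlap(p, p) == 1.0

    def test_disjoint_supports_give_zero(self):
        p1 = np.zeros((10, 10))
        p2 = np.zeros((10, 10))
        p1[:5] = 1 / 50
        p2[5:] = 1 / 50
        assert ov.degree_of_overlap(p1, p2) == 0.0

    def test_symmetry_exact(self, rng):
        a = rng.random((20, 20))
        b = rng.random((20, 20))
        a /= a.sum()
        b /= b.sum()
        assert ov.degree_of_overlap(a, b) == ov.degree_of_overlap(b, a)

    def test_half_overlapping_uniform_gives_sqrt_half(self):
        p1 = np.zeros(40)
        p2 = np.zeros(40)
        p1[:20] = 1 / 20          # uniform over A ∪ B
        p2[10:20] = 1 / 10        # uniform over B, |A| = |B|
        assert ov.degree_of_overlap(p1, p2) == pytest.approx(np.sqrt(0.5))

    def test_lattice_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ov.degree_of_overlap(np.full(4, 0.25), np.full(5, 0.2))

    def test_relabeling_invariance(self, rng):
        a = rng.random(100)
        b = rng.random(100)
        a /= a.sum()
        b /= b.sum()
        perm = rng.permutation(100)
        assert ov.degree_of_overlap(a[perm], b[perm]) == pytest.approx(
            ov.degree_of_overlap(a, b), abs=1e-15)


class TestPopulationOverlap:
    def _store(self, arr):
        n = arr.shape[0]
        return pp.SegmentStore(arr, np.array(["AF"] * n, dtype=object),
                               np.array(["real"] * n, dtype=object),
                               np.array([f"p{i}" for i in range(n)], dtype=object),
                               100.0, arr.shape[-1] / 100.0)

    def test_identical_populations_high_do(self, rng):
        arr = rng.normal(size=(40, 100))
        res = ov.population_overlap(self._store(arr), self._store(arr.copy()),
                                    perplexity=10, iters=250, seed=2)
        assert res.do > 0.99

    def test_af_vs_sr_below_af_vs_af(self, rng):
        af1 = rng.normal(size=(30, 80))
        af2 = rng.normal(size=(30, 80))
        sr = rng.normal(size=(30, 80)) + 4.0
        same = ov.population_overlap(self._store(af1), self._store(af2),
                                     perplexity=10, iters=250, seed=3).do
        diff = ov.population_overlap(self._store(af1), self._store(sr),
                                     perplexity=10, iters=250, seed=3).do
        assert diff < same

    def test_seeded_determinism(self, rng):
        a = rng.normal(size=(20, 40))
        b = rng.normal(size=(20, 40))
        r1 = ov.population_overlap(self._store(a), self._store(b),
                                   perplexity=6, iters=120, seed=5).do
        r2 = ov.population_overlap(self._store(a), self._store(b),
                                   perplexity=6, iters=120, seed=5).do
        assert r1 == r2
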