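"""t-SNE embedding, kernel-density estimation and the Degree-of-Overlap statistic.

t-SNE is implemented from first principles: Gaussian conditional affinities
p_{j|i} with per-point bandwidths sigma_i found by perplexity-matching
bisection, symmetrized joint affinities p_ij = (p_{i|j} + p_{j|i}) / (2n),
Student-t low-dimensional affinities q_ij, and gradient descent on the
Kullback–Leibler divergence C(Y) = KL(P||Q) with the exact gradient

    dC/dy_i = 4 * sum_j (p_ij - q_ij) * q_ij * Z * (y_i - y_j),

where Z = sum_{k != l} (1 + ||y_k - y_l||^2)^{-1}. The optimizer follows the
original recipe: momentum 0.5 switching to 0.8, early exaggeration (x4 for
the first 50 iterations) and per-component adaptive gains.

Two embedded populations are compared by estimating a Gaussian kernel density
for each on a shared lattice and summing the Bhattacharyya coefficient over
cells: DO = sum sqrt(P1 * P2), which is 1 for identical densities and 0 for
disjoint ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .preprocess import SegmentStore

__all__ = [
    "AffinityMatrix",
    "Embedding",
    "OverlapGrid",
    "OverlapResult",
    "compute_affinities",
    "kl_cost",
    "kl_gradient",
    "tsne_embed",
    "silverman_bandwidth",
    "kde2d",
    "degree_of_overlap",
    "population_overlap",
]

_EPS = 1e-12


@dataclass
class AffinityMatrix:
    p: np.ndarray          # n x n symmetric joint probabilities, zero diagonal
    sigma: np.ndarray      # per-point Gaussian bandwidths
    perplexity: float


@dataclass
class Embedding:
    y: np.ndarray          # n x s coordinates
    kl_history: np.ndarray
    seed: int


@dataclass(frozen=True)
class OverlapGrid:
    """A shared 2-D lattice: per-axis bounds and resolution."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    resolution: int = 100

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        dx = (self.x_max - self.x_min) / self.resolution
        dy = (self.y_max - self.y_min) / self.resolution
        cx = self.x_min + dx * (np.arange(self.resolution) + 0.5)
        cy = self.y_min + dy * (np.arange(self.resolution) + 0.5)
        return cx, cy


@dataclass
class OverlapResult:
    grid: OverlapGrid
    p1: np.ndarray
    p2: np.ndarray
    do: float
    embedding: Embedding | None = None
    split: int | None = None  # index separating population 1 from 2 in y


def _sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _cond_probs(d_row: np.ndarray, beta: float, i: int) -> tuple[np.ndarray, float]:
    """Conditional p_{j|i} at precision beta = 1/(2 sigma_i^2); returns (p, entropy)."""
    logits = -d_row * beta
    logits[i] = -np.inf
    logits -= logits[~np.isneginf(logits)].max(initial=0.0)
    e = np.exp(logits)
    s = e.sum()
    if s == 0.0:  # beta overshoot: collapse to the nearest neighbour(s)
        nearest = d_row == np.min(np.delete(d_row, i))
        nearest[i] = False
        e = nearest.astype(float)
        s = e.sum()
    p = e / s
    # Shannon entropy in nats; perplexity = exp(H)
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return p, h


def compute_affinities(x: np.ndarray, perplexity: float = 30.0,
                       tol: float = 1e-4, max_iter: int = 200) -> AffinityMatrix:
    """Symmetrized joint affinities with perplexity-matched bandwidths.

    For each point a bisection on the Gaussian precision finds sigma_i such
    that the conditional distribution's perplexity matches the target within
    ``tol``. Duplicate points (zero distances) are permitted.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    d = _sq_dists(x)
    target_h = np.log(perplexity)
    cond = np.zeros((n, n))
    sigma = np.zeros(n)
    for i in range(n):
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(max_iter):
            p, h = _cond_probs(d[i].copy(), beta, i)
            if abs(h - target_h) < tol:
                break
            if h > target_h:     # too flat: increase precision
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (lo + hi) / 2.0
        cond[i] = p
        sigma[i] = np.sqrt(1.0 / (2.0 * beta))
    pj = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(pj, 0.0)
    return AffinityMatrix(p=pj, sigma=sigma, perplexity=perplexity)


def _q_matrix(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Student-t affinities: returns (q, num, Z) with num = (1+||yi-yj||^2)^-1."""
    num = 1.0 / (1.0 + _sq_dists(y))
    np.fill_diagonal(num, 0.0)
    z = num.sum()
    q = num / z
    return q, num, z


def kl_cost(p: np.ndarray, y: np.ndarray) -> float:
    """C(Y) = KL(P||Q) = sum_{i != j} p_ij log(p_ij / q_ij)."""
    q, _, _ = _q_matrix(y)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], _EPS))))


def kl_gradient(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact gradient dC/dy_i = 4 sum_j (p_ij - q_ij) q_ij Z (y_i - y_j)."""
    q, num, _ = _q_matrix(y)
    # q_ij * Z == num_ij, so the weight is (p_ij - q_ij) * num_ij.
    w = (p - q) * num
    grad = 4.0 * (np.diag(w.sum(axis=1)) - w) @ y
    return grad


def tsne_embed(x: np.ndarray, s: int = 2, perplexity: float = 30.0,
               iters: int = 500, seed: int = 0,
               learning_rate: float | str = "auto",
               early_exaggeration: float = 4.0, exaggeration_iters: int = 50,
               momentum_switch: int = 250,
               affinities: AffinityMatrix | None = None) -> Embedding:
    """Embed ``x`` into ``s`` dimensions by gradient descent on KL(P||Q).

    Momentum starts at 0.5 and switches to 0.8 at ``momentum_switch``;
    affinities are multiplied by ``early_exaggeration`` for the first
    ``exaggeration_iters`` iterations; per-component adaptive gains follow
    the original descent recipe. ``learning_rate="auto"`` scales with the
    sample count, ``max(n / early_exaggeration / 4, 50)`` — a fixed large
    step badly under-converges small problems. Raises on a non-finite cost,
    reporting the iteration index.
    """
    aff = affinities if affinities is not None else compute_affinities(x, perplexity)
    p = aff.p
    n = p.shape[0]
    if learning_rate == "auto":
        learning_rate = max(n / early_exaggeration / 4.0, 50.0)
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, 1e-4, size=(n, s))
    velocity = np.zeros_like(y)
    gains = np.ones_like(y)
    history = np.empty(iters)
    for it in range(iters):
        p_eff = p * early_exaggeration if it < exaggeration_iters else p
        p_eff = p_eff / p_eff.sum() if it < exaggeration_iters else p_eff
        grad = kl_gradient(p_eff, y)
        momentum = 0.5 if it < momentum_switch else 0.8
        gains = np.where(np.sign(grad) != np.sign(velocity), gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        velocity = momentum * velocity - learning_rate * gains * grad
        y = y + velocity
        y = y - y.mean(axis=0)
        cost = kl_cost(p, y)
        if not np.isfinite(cost):
            raise FloatingPointError(f"t-SNE diverged at iteration {it}")
        history[it] = cost
    return Embedding(y=y, kl_history=history, seed=seed)


def silverman_bandwidth(y: np.ndarray) -> np.ndarray:
    """Silverman's rule per dimension: h_j = sd_j * n^(-1/(d+4))."""
    y = np.asarray(y, dtype=float)
    n, d = y.shape
    sd = y.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-3)
    return sd * n ** (-1.0 / (d + 4))


def make_grid(y: np.ndarray, bandwidth: np.ndarray, resolution: int = 100,
              margin_bw: float = 3.0) -> OverlapGrid:
    """Lattice covering all points with a margin of ``margin_bw`` bandwidths."""
    lo = y.min(axis=0) - margin_bw * bandwidth
    hi = y.max(axis=0) + margin_bw * bandwidth
    return OverlapGrid(float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]),
                       resolution)


def kde2d(y: np.ndarray, grid: OverlapGrid,
          bandwidth: np.ndarray | float | None = None) -> np.ndarray:
    """Gaussian-kernel density on the lattice, returned as cell masses.

    The product (separable) normal kernel is evaluated at cell centers and
    converted to per-cell probability masses summing to 1. ``bandwidth`` may
    be a scalar, a per-dimension pair, or None for Silverman's rule. A
    degenerate cloud (all points identical) yields a delta-like mass with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be n x 2")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if np.all(np.ptp(y, axis=0) == 0):
        warnings.warn("degenerate point cloud; density collapses to one cell",
                      stacklevel=2)
    if bandwidth is None:
        h = silverman_bandwidth(y)
    else:
        h = np.broadcast_to(np.asarray(bandwidth, dtype=float), (2,)).copy()
    h = np.maximum(h, 1e-9)
    cx, cy = grid.centers()
    gx = np.exp(-0.5 * ((cx[None, :] - y[:, 0:1]) / h[0]) ** 2)
    gy = np.exp(-0.5 * ((cy[None, :] - y[:, 1:2]) / h[1]) ** 2)
    density = gx.T @ gy  # (res, res): sum over points of separable kernels
    total = density.sum()
    if total <= 0:
        raise ValueError("grid does not cover the point cloud")
    return density / total


def degree_of_overlap(p1: np.ndarray, p2: np.ndarray) -> float:
    """Bhattacharyya coefficient DO = sum sqrt(P1 * P2) over shared cells.

    1 for identical cell-mass distributions, 0 for disjoint supports;
    clipped to [0, 1] against floating-point rounding.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("cell-mass grids must share one lattice")
    if not (np.isclose(p1.sum(), 1.0, atol=1e-6) and np.isclose(p2.sum(), 1.0, atol=1e-6)):
        raise ValueError("cell masses must each sum to 1")
    return float(np.clip(np.sum(np.sqrt(p1 * p2)), 0.0, 1.0))


def population_overlap(real_segs: SegmentStore, gen_segs: SegmentStore,
                       perplexity: float = 30.0, iters: int = 500, seed: int = 0,
                       resolution: int = 100, max_per_population: int = 2000) -> OverlapResult:
    """Joint t-SNE of two segment populations and their density overlap.

    Both populations are embedded together (a shared 2-D space is required
    for DO to be meaningful), then one kernel density per population is
    estimated on a shared lattice whose bandwidth is Silverman's rule on the
    combined embedding. Populations larger than ``max_per_population`` are
    subsampled with the run seed.
    """
    def _vectors(store: SegmentStore) -> np.ndarray:
        arr = store.channel("ppg") if store.n_channels > 1 else store.segments
        return np.asarray(arr, dtype=float).reshape(len(store), -1)

    a = _vectors(real_segs)
    b = _vectors(gen_segs)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both stores must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("stores must share the vector length")
    rng = np.random.default_rng(seed)
    if a.shape[0] > max_per_population:
        a = a[rng.choice(a.shape[0], max_per_population, replace=False)]
    if b.shape[0] > max_per_population:
        b = b[rng.choice(b.shape[0], max_per_population, replace=False)]
    x = np.vstack([a, b])
    emb = tsne_embed(x, perplexity=perplexity, iters=iters, seed=seed)
    split = a.shape[0]
    y1, y2 = emb.y[:split], emb.y[split:]
    h = silverman_bandwidth(emb.y)
    grid = make_grid(emb.y, h, resolution=resolution)
    p1 = kde2d(y1, grid, bandwidth=h)
    p2 = kde2d(y2, grid, bandwidth=h)
    return OverlapResult(grid=grid, p1=p1, p2=p2,
                         do=degree_of_overlap(p1, p2),
                         embedding=emb, split=split)
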