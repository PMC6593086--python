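"""Low-dimensional projections of dihedral trajectories.

Five embedding strategies are provided, all as scikit-learn style estimators:

* :class:`DihedralPCA` — PCA of the sin/cos (unit-circle) representation of
  the angles, the standard periodicity-aware variant of PCA (dPCA).  The only
  method that does not consume the periodic dissimilarity matrix.
* :class:`StressEmbedding` — direct minimization of the metric-MDS stress
  chi = sum_{i != j} (R_ij - r_ij)^2 with conjugate gradients ("dist. match").
* :class:`GeodesicIsomap` — k-NN graph geodesics (Dijkstra) followed by
  classical scaling.
* :class:`LaplacianEigenmaps` — Gaussian-kernel graph Laplacian, generalized
  eigenproblem L v = lambda Deg v, smallest non-trivial eigenvectors.
* :class:`ExactTSNE` — exact O(N^2) t-SNE with per-point bandwidths
  calibrated to a target perplexity by bisection.

Each estimator accepts either an ``(N, M)`` angle matrix (periodic
dissimilarities are computed internally) or a precomputed dissimilarity
matrix via ``dissimilarity="precomputed"``.  Deterministic methods fix the
sign of every eigenvector so that its largest-magnitude entry is positive,
making outputs bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .angles import (
    DissimilarityMatrix,
    _as_angle_array,
    pairwise_dissimilarity,
    sincos_embed,
)


@dataclass
class Projection:
    """N x d coordinates produced by an embedding, with provenance."""

    coords: np.ndarray
    method_tag: str
    params: dict = field(default_factory=dict)
    loss_trace: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("projection coords must be 2-D (N, d)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projection coords must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[1]


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] *= -1.0
    return V


def _resolve_D(X, dissimilarity: str) -> np.ndarray:
    if dissimilarity == "precomputed":
        if isinstance(X, DissimilarityMatrix):
            return X.values
        return DissimilarityMatrix(np.asarray(X, dtype=float)).values
    if dissimilarity == "periodic":
        if isinstance(X, DissimilarityMatrix):
            return X.values
        return pairwise_dissimilarity(X).values
    raise ValueError(f"unknown dissimilarity mode {dissimilarity!r}")


def classical_mds(D: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (Torgerson) of a distance matrix.

    Double-centers ``-D^2 / 2``, takes the top-``d`` eigenpairs and returns
    ``(coords, eigenvalues)``.  Negative eigenvalues (non-Euclidean input)
    contribute zero-variance axes.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = 0.5 * (B + B.T)
    w, V = scipy.linalg.eigh(B)
    order = np.argsort(w)[::-1][:d]
    w_top = w[order]
    V_top = _fix_eigvec_signs(V[:, order])
    scale = np.sqrt(np.clip(w_top, 0.0, None))
    return V_top * scale[None, :], w_top


# ---------------------------------------------------------------------------
# dPCA
# ---------------------------------------------------------------------------

class DihedralPCA(TransformerMixin, BaseEstimator):
    """PCA on the sin/cos embedding of dihedral angles (dPCA).

    Because the projection is orthogonal onto a linear subspace of the chord
    (sin/cos) space, distances between projected points are never larger than
    the chord distances, which in turn never exceed the periodic arc
    dissimilarities — the projection contracts all pairs.

    Parameters
    ----------
    n_components : int, default 2
        Output dimensionality d (2 for planar maps, 3 for spatial ones).

    Attributes
    ----------
    components_ : (d, 2M) array of principal axes in sin/cos space.
    explained_variance_ : (d,) eigenvalues of the covariance, non-increasing.
    mean_ : (2M,) column means of the sin/cos matrix.
    embedding_ : (N, d) projection of the training frames.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        x = _as_angle_array(X)
        n, m = x.shape
        d = self.n_components
        if d < 1:
            raise ValueError("n_components must be >= 1")
        if d >= 2 * m:
            raise ValueError(f"n_components={d} must be < 2M = {2 * m}")
        if n <= d:
            raise ValueError(f"need more frames (N={n}) than components (d={d})")
        Z = sincos_embed(x)
        self.mean_ = Z.mean(axis=0)
        Zc = Z - self.mean_
        C = (Zc.T @ Zc) / n
        w, V = scipy.linalg.eigh(C)
        order = np.argsort(w)[::-1][:d]
        self.explained_variance_ = np.clip(w[order], 0.0, None)
        self.components_ = _fix_eigvec_signs(V[:, order]).T
        self.embedding_ = Zc @ self.components_.T
        return self.embedding_

    def transform(self, X):
        x = _as_angle_array(X)
        return (sincos_embed(x) - self.mean_) @ self.components_.T


# ---------------------------------------------------------------------------
# Metric MDS by direct stress minimization ("dist. match")
# ---------------------------------------------------------------------------

def _stress_value(coords: np.ndarray, D: np.ndarray) -> float:
    r = _euclidean_distances(coords)
    diff = D - r
    return float(np.sum(diff * diff))  # ordered pairs i != j count twice


def _euclidean_distances(coords: np.ndarray) -> np.ndarray:
    g = coords @ coords.T
    sq = np.diag(g)
    r2 = np.clip(sq[:, None] + sq[None, :] - 2 * g, 0.0, None)
    r = np.sqrt(r2)
    np.fill_diagonal(r, 0.0)
    return r


def _stress_grad(coords: np.ndarray, D: np.ndarray) -> np.ndarray:
    r = _euclidean_distances(coords)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(r > 0, (r - D) / r, 0.0)
    # chi = 2 * sum_{i<j} (D_ij - r_ij)^2 ; d chi / d x_i = 4 sum_j w_ij (x_i - x_j)
    grad = 4.0 * (coords * w.sum(axis=1)[:, None] - w @ coords)
    return grad


class StressEmbedding(TransformerMixin, BaseEstimator):
    """Metric multidimensional scaling by direct stress minimization.

    Minimizes ``chi = sum_{i != j} (R_ij - r_ij)^2`` over the projected
    coordinates with conjugate gradients, starting from the classical-MDS
    solution (deterministic) or from seeded Gaussian noise.

    Attributes
    ----------
    embedding_ : (N, d) coordinates at the (local) minimum.
    stress_ : final value of chi.
    loss_trace_ : chi after every optimizer iteration (non-increasing).
    """

    def __init__(self, n_components: int = 2, dissimilarity: str = "periodic",
                 init: str = "classical", random_state: int = 0,
                 max_iter: int = 5000, tol: float = 1e-9):
        self.n_components = n_components
        self.dissimilarity = dissimilarity
        self.init = init
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        D = _resolve_D(X, self.dissimilarity)
        n = D.shape[0]
        d = self.n_components
        if n < 2:
            raise ValueError("need at least 2 frames")
        if self.init == "classical":
            x0, _ = classical_mds(D, d)
        elif self.init == "random":
            rng = np.random.default_rng(self.random_state)
            x0 = rng.standard_normal((n, d)) * D.max() / np.sqrt(n)
        else:
            raise ValueError(f"unknown init {self.init!r}")

        trace = [_stress_value(x0, D)]

        def fun(flat):
            c = flat.reshape(n, d)
            return _stress_value(c, D), _stress_grad(c, D).ravel()

        def cb(flat):
            val = _stress_value(flat.reshape(n, d), D)
            prev = trace[-1]
            trace.append(val)
            scale = max(abs(prev), 1e-30)
            if abs(prev - val) < self.tol * scale:
                raise StopIteration

        res = scipy.optimize.minimize(
            fun, x0.ravel(), jac=True, method="CG", callback=cb,
            options={"maxiter": self.max_iter, "gtol": 1e-12},
        )
        coords = res.x.reshape(n, d)
        final = _stress_value(coords, D)
        if final > trace[0]:  # optimizer never worsens the start
            coords, final = x0, trace[0]
        trace.append(final)
        self.embedding_ = coords
        self.stress_ = final
        self.loss_trace_ = np.minimum.accumulate(np.asarray(trace))
        self.n_iter_ = res.nit
        return self

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self.embedding_


# ---------------------------------------------------------------------------
# Neighbor graphs, isomap, Laplacian eigenmaps
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Symmetrized k-nearest-neighbor graph over trajectory frames."""

    edges: list
    k: int
    n: int

    def adjacency(self) -> sp.csr_matrix:
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        i, j, w = zip(*self.edges)
        A = sp.coo_matrix((w, (i, j)), shape=(self.n, self.n))
        A = A.maximum(A.T)
        return A.tocsr()


def knn_graph(D: np.ndarray, k: int) -> NeighborGraph:
    """k-NN graph from a dissimilarity matrix, symmetrized by union
    (an edge is kept if either endpoint lists the other)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        k = n - 1
    edges = []
    order = np.argsort(D, axis=1, kind="stable")
    for i in range(n):
        neigh = [j for j in order[i] if j != i][:k]
        for j in neigh:
            edges.append((i, int(j), float(D[i, j])))
    return NeighborGraph(edges=edges, k=k, n=n)


def _check_connected(A: sp.spmatrix):
    ncomp, labels = connected_components(A, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"neighbor graph is disconnected: {ncomp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)}; increase k"
        )


class GeodesicIsomap(TransformerMixin, BaseEstimator):
    """Isomap: classical scaling of graph geodesic distances.

    Builds the union-symmetrized k-NN graph on the periodic dissimilarities,
    computes all-pairs shortest paths with Dijkstra, and applies classical
    MDS to the geodesic matrix.  A disconnected graph raises an error naming
    the component sizes rather than silently embedding the largest component.
    """

    def __init__(self, n_neighbors: int = 15, n_components: int = 2,
                 dissimilarity: str = "periodic"):
        self.n_neighbors = n_neighbors
        self.n_components = n_components
        self.dissimilarity = dissimilarity

    def fit(self, X, y=None):
        D = _resolve_D(X, self.dissimilarity)
        graph = knn_graph(D, self.n_neighbors)
        A = graph.adjacency()
        _check_connected(A)
        G = shortest_path(A, method="D", directed=False)
        coords, evals = classical_mds(G, self.n_components)
        self.graph_ = graph
        self.geodesics_ = G
        self.eigenvalues_ = evals
        self.embedding_ = coords
        return self

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self.embedding_


class LaplacianEigenmaps(TransformerMixin, BaseEstimator):
    """Spectral embedding from the Gaussian-kernel graph Laplacian.

    Edge weights are ``w_ij = exp(-gamma * D_ij^2)`` on the union-symmetrized
    k-NN graph.  Coordinates are the eigenvectors of the generalized problem
    ``L v = lambda Deg v`` (L = Deg - W) for the d smallest non-zero
    eigenvalues; the zero eigenvalue's constant eigenvector is discarded.
    """

    def __init__(self, n_neighbors: int = 15, kernel_gamma: float = 1.0,
                 n_components: int = 2, dissimilarity: str = "periodic"):
        self.n_neighbors = n_neighbors
        self.kernel_gamma = kernel_gamma
        self.n_components = n_components
        self.dissimilarity = dissimilarity

    def fit(self, X, y=None):
        if self.kernel_gamma <= 0:
            raise ValueError("kernel_gamma must be > 0")
        D = _resolve_D(X, self.dissimilarity)
        graph = knn_graph(D, self.n_neighbors)
        A = graph.adjacency()
        _check_connected(A)
        W = A.toarray()
        mask = W > 0
        W[mask] = np.exp(-self.kernel_gamma * W[mask] ** 2)
        deg = W.sum(axis=1)
        L = np.diag(deg) - W
        w, V = scipy.linalg.eigh(L, np.diag(deg))
        # first eigenvalue is 0 (constant eigenvector); take the next d
        d = self.n_components
        take = np.argsort(w)[1:d + 1]
        self.eigenvalues_ = w[take]
        self.embedding_ = _fix_eigvec_signs(V[:, take])
        self.graph_ = graph
        return self

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self.embedding_


# ---------------------------------------------------------------------------
# Exact t-SNE
# ---------------------------------------------------------------------------

def tsne_affinities(D: np.ndarray, perplexity: float, tol: float = 1e-5,
                    max_bisect: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized t-SNE affinities ``p_ij`` from a distance matrix.

    Per-point precisions ``beta_i = 1 / (2 sigma_i^2)`` are calibrated by
    bisection so that the perplexity ``2^H(P_i)`` of every conditional
    distribution matches the target within ``tol``.

    Returns ``(P, conditional_perplexities)``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 < perplexity < n:
        raise ValueError(f"perplexity={perplexity} must satisfy 1 < perplexity < N={n}")
    target_entropy = np.log2(perplexity)
    D2 = D ** 2
    P = np.zeros((n, n))
    perp_out = np.zeros(n)
    for i in range(n):
        d2 = np.delete(D2[i], i)
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        for _ in range(max_bisect):
            w = np.exp(-(d2 - d2.min()) * beta)
            sw = w.sum()
            p = w / sw
            nz = p > 0
            H = -np.sum(p[nz] * np.log2(p[nz]))
            if abs(H - target_entropy) < np.log2(1 + tol / perplexity):
                break
            if H > target_entropy:  # too flat -> increase beta
                beta_lo = beta
                beta = beta * 2 if np.isinf(beta_hi) else 0.5 * (beta + beta_hi)
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0 else 0.5 * (beta + beta_lo)
        perp_out[i] = 2.0 ** H
        row = np.zeros(n)
        row[np.arange(n) != i] = p
        P[i] = row
    P = (P + P.T) / (2.0 * n)
    np.maximum(P, 1e-12, out=P)
    np.fill_diagonal(P, 0.0)
    P /= P.sum()
    return P, perp_out


class ExactTSNE(TransformerMixin, BaseEstimator):
    """Exact (non-approximated) t-distributed stochastic neighbor embedding.

    Gradient descent on KL(P || Q) with early exaggeration and momentum;
    the Student-t kernel with one degree of freedom defines Q in the
    low-dimensional space.  All randomness (the small Gaussian
    initialization) is controlled by ``random_state``.
    """

    def __init__(self, perplexity: float = 110.0, n_components: int = 2,
                 dissimilarity: str = "periodic", random_state: int = 0,
                 n_iter: int = 1000, learning_rate: float = 200.0,
                 early_exaggeration: float = 12.0, exaggeration_iter: int = 250):
        self.perplexity = perplexity
        self.n_components = n_components
        self.dissimilarity = dissimilarity
        self.random_state = random_state
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.early_exaggeration = early_exaggeration
        self.exaggeration_iter = exaggeration_iter

    def fit(self, X, y=None):
        D = _resolve_D(X, self.dissimilarity)
        n = D.shape[0]
        P, cond_perp = tsne_affinities(D, self.perplexity)
        self.conditional_perplexities_ = cond_perp
        rng = np.random.default_rng(self.random_state)
        d = self.n_components
        Y = rng.standard_normal((n, d)) * 1e-4
        dY = np.zeros_like(Y)
        trace = []
        for it in range(self.n_iter):
            exag = self.early_exaggeration if it < self.exaggeration_iter else 1.0
            momentum = 0.5 if it < self.exaggeration_iter else 0.8
            r2 = _euclidean_distances(Y) ** 2
            num = 1.0 / (1.0 + r2)
            np.fill_diagonal(num, 0.0)
            Q = num / num.sum()
            np.maximum(Q, 1e-12, out=Q)
            PQ = (exag * P - Q) * num
            grad = 4.0 * (Y * PQ.sum(axis=1)[:, None] - PQ @ Y)
            dY = momentum * dY - self.learning_rate * grad
            Y = Y + dY
            Y = Y - Y.mean(axis=0)
            mask = P > 0
            kl = float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
            trace.append(kl)
        self.embedding_ = Y
        self.loss_trace_ = np.asarray(trace)
        return self

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self.embedding_


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def dpca_project(traj, d: int = 2) -> Projection:
    est = DihedralPCA(n_components=d)
    coords = est.fit_transform(traj)
    return Projection(coords, "dpca", {"n_components": d})


def stress_minimize(D, d: int = 2, seed: int = 0, max_iter: int = 5000,
                    tol: float = 1e-9, init: str = "classical") -> Projection:
    est = StressEmbedding(n_components=d, dissimilarity="precomputed",
                          init=init, random_state=seed, max_iter=max_iter, tol=tol)
    est.fit(D)
    return Projection(est.embedding_, "dist_match",
                      {"n_components": d, "seed": seed, "stress": est.stress_},
                      loss_trace=est.loss_trace_)


def isomap_project(D, k: int = 15, d: int = 2) -> Projection:
    est = GeodesicIsomap(n_neighbors=k, n_components=d, dissimilarity="precomputed")
    est.fit(D)
    return Projection(est.embedding_, "isomap", {"n_neighbors": k, "n_components": d})


def laplacian_eigenmaps_project(D, k: int = 15, gamma: float = 1.0,
                                d: int = 2) -> Projection:
    est = LaplacianEigenmaps(n_neighbors=k, kernel_gamma=gamma, n_components=d,
                             dissimilarity="precomputed")
    est.fit(D)
    return Projection(est.embedding_, "laplacian_eigenmaps",
                      {"n_neighbors": k, "kernel_gamma": gamma, "n_components": d})


def tsne_project(D, perplexity: float = 110.0, d: int = 2, seed: int = 0,
                 iters: int = 1000, learning_rate: float = 200.0) -> Projection:
    est = ExactTSNE(perplexity=perplexity, n_components=d,
                    dissimilarity="precomputed", random_state=seed,
                    n_iter=iters, learning_rate=learning_rate)
    est.fit(D)
    return Projection(est.embedding_, "tsne",
                      {"perplexity": perplexity, "n_components": d, "seed": seed},
                      loss_trace=est.loss_trace_)
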