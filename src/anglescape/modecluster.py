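"""Density-based basin identification on the torus (PAMM-style).

The free-energy basins sampled by a trajectory appear as modes of the
probability density over dihedral space.  They are located in four steps:

1. **Sparse grid** — farthest-point sampling picks m frames that cover the
   sampled region uniformly.
2. **KDE** — the density at every grid point is estimated with a wrapped
   Gaussian kernel (periodic images truncated at +/- one period per
   coordinate, an error below 1e-8 for bandwidths under ~1 rad).
3. **Quick-Shift** — every grid point is linked to the *nearest* grid point
   with strictly higher density within a cutoff distance lambda; points with
   no such neighbor are density modes (roots of the resulting forest).
4. **Assignment** — every trajectory frame inherits the mode of its nearest
   grid point.

Per-cluster covariance diagnostics summarize basin shape: the covariance is
computed about the per-coordinate circular mean using minimal-image
residuals, and from its eigenvalue spectrum {lambda_k} we report the
determinant (scaled so the largest-determinant cluster reads 1), the
fraction of variance captured by the top two eigenvalues, and the effective
dimensionality

    D_i = exp(- sum_k eta_k log eta_k),   eta_k = lambda_k / sum_j lambda_j,

the exponential of the spectral Shannon entropy (participation ratio):
a flat spectrum of rank R gives D = R, a one-dimensional basin gives D = 1.

Bootstrap resampling quantifies which modes are statistically robust: the
trajectory is resampled with replacement and reclustered; two reference
clusters "merge" in a replicate when the majority of each one's resampled
frames land in the same bootstrap mode.  One minus the merge frequency is a
distance in [0, 1] on which an average-linkage dendrogram is built; cutting
it yields macro-clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, ClusterMixin

from .angles import (
    DissimilarityMatrix,
    TWO_PI,
    _as_angle_array,
    pairwise_dissimilarity,
    periodic_difference,
)
from .landmarks import fps_select

try:  # JIT fast path mirroring the numpy wrapped-kernel sum below
    import numba as _numba

    @_numba.njit(cache=False)
    def _kde_kernel(xg, x, h2):
        g, m = xg.shape
        n = x.shape[0]
        out = np.zeros(g)
        for a in range(g):
            total = 0.0
            for i in range(n):
                prod = 1.0
                for k in range(m):
                    d = abs(xg[a, k] - x[i, k])
                    if d > np.pi:
                        d = TWO_PI - d
                    prod *= (np.exp(-d * d / h2)
                             + np.exp(-(d - TWO_PI) ** 2 / h2)
                             + np.exp(-(d + TWO_PI) ** 2 / h2))
                    if prod < 1e-290:  # far frame: contribution is zero
                        prod = 0.0
                        break
                total += prod
            out[a] = total
        return out

except ImportError:  # pragma: no cover
    _kde_kernel = None


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Grid, densities, Quick-Shift links, and mode labels for a trajectory."""

    grid_indices: np.ndarray
    densities: np.ndarray
    parent: np.ndarray          # index into grid positions; self-link = root
    mode_of_grid: np.ndarray    # mode label per grid point (0..n_modes-1)
    mode_of_frame: np.ndarray   # mode label per trajectory frame
    bandwidth: float
    lambda_cut: float

    @property
    def n_modes(self) -> int:
        return int(self.mode_of_grid.max()) + 1

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent == np.arange(self.parent.size))


@dataclass
class ClusterStats:
    """Per-cluster covariance-spectrum diagnostics."""

    labels: np.ndarray            # cluster ids, sorted
    counts: np.ndarray
    eigenvalues: list             # per cluster, non-increasing spectrum
    scaled_determinant: np.ndarray
    top2_fraction: np.ndarray
    eff_dimension: np.ndarray
    flagged: np.ndarray           # True: too few frames or wide (residual > pi/2)


@dataclass
class ClusterHierarchy:
    """Bootstrap merge distances and the dendrogram built on them."""

    merge_distance: np.ndarray    # (n_clusters, n_clusters), 1 - merge frequency
    linkage: np.ndarray           # scipy linkage matrix (average linkage)
    cluster_labels: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.cluster_labels is None:
            self.cluster_labels = np.arange(self.merge_distance.shape[0])

    def to_newick(self) -> str:
        """Newick rendering of the dendrogram over cluster labels."""
        tree = sch.to_tree(self.linkage)
        labels = self.cluster_labels

        def walk(node):
            if node.is_leaf():
                return f"c{labels[node.id]}"
            return (f"({walk(node.left)}:{node.dist / 2:.6f},"
                    f"{walk(node.right)}:{node.dist / 2:.6f})")

        return walk(tree) + ";"


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def build_grid(D, m: int, seed: int = 0) -> np.ndarray:
    """Select ``m`` grid frames by farthest point sampling; the start frame
    is drawn uniformly from the seed so independent runs cover the space
    from different anchors."""
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    n = Dv.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"grid size m={m} must satisfy 1 <= m <= N={n}")
    start = int(np.random.default_rng(seed).integers(n))
    return fps_select(Dv, m, start=start).indices


def kde_on_grid(traj, grid, bandwidth: float, chunk: int = 64) -> np.ndarray:
    """Wrapped-Gaussian kernel density at each grid point.

    density(g) = (1/N) sum_i prod_c [ phi_h(d_c) + phi_h(d_c - 2pi)
                                       + phi_h(d_c + 2pi) ]
    where d_c is the per-coordinate minimal-image difference and phi_h the
    normalized Gaussian kernel of width ``bandwidth``.  Strictly positive
    because every grid point is itself a frame.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    x = _as_angle_array(traj)
    n, m = x.shape
    grid = np.asarray(grid, dtype=int)
    h2 = 2.0 * bandwidth ** 2
    log_norm = -m * np.log(bandwidth * np.sqrt(2.0 * np.pi))
    if _kde_kernel is not None and grid.size * n * m > 500_000:
        dens = _kde_kernel(np.ascontiguousarray(x[grid]),
                           np.ascontiguousarray(x), h2)
        return dens * np.exp(log_norm) / n
    dens = np.empty(grid.size)
    for g0 in range(0, grid.size, chunk):
        gs = grid[g0:g0 + chunk]
        diff = np.abs(x[gs][:, None, :] - x[None, :, :])
        np.minimum(diff, TWO_PI - diff, out=diff)  # |d_c| in [0, pi]
        k = (np.exp(-diff ** 2 / h2)
             + np.exp(-(diff - TWO_PI) ** 2 / h2)
             + np.exp(-(diff + TWO_PI) ** 2 / h2))
        dens[g0:g0 + chunk] = np.prod(k, axis=2).sum(axis=1)
    return dens * np.exp(log_norm) / n


def default_bandwidth(D_grid: np.ndarray) -> float:
    """Half the median nearest-neighbor distance among grid points."""
    Dg = np.asarray(D_grid, dtype=float)
    if Dg.shape[0] < 2:
        raise ValueError("need at least 2 grid points for the bandwidth rule")
    off = Dg + np.diag(np.full(Dg.shape[0], np.inf))
    nn = off.min(axis=1)
    return 0.5 * float(np.median(nn))


def quick_shift(grid, densities, D, lambda_cut: float):
    """Link every grid point to its nearest strictly-denser grid neighbor
    within ``lambda_cut``; unlinked points are density modes.

    Parameters
    ----------
    grid : grid frame indices (used to slice ``D`` when ``D`` is N x N).
    densities : positive densities at the grid points.
    D : either the full N x N dissimilarity matrix or the m x m grid block.
    lambda_cut : maximum link length ("stopping criterion").

    Returns ``(parent, mode_of_grid)``: parent links into grid positions
    (self-link marks a root) and the mode label of every grid point.
    """
    dens = np.asarray(densities, dtype=float)
    if np.any(dens <= 0):
        raise ValueError("densities must be strictly positive")
    if lambda_cut <= 0:
        raise ValueError("lambda_cut must be > 0")
    grid = np.asarray(grid, dtype=int)
    Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    if Dv.shape[0] == grid.size and Dv.shape[1] == grid.size:
        Dg = Dv
    else:
        Dg = Dv[np.ix_(grid, grid)]
    m = grid.size
    parent = np.arange(m)
    for i in range(m):
        higher = dens > dens[i]
        higher[i] = False
        cand = np.flatnonzero(higher & (Dg[i] <= lambda_cut))
        if cand.size:
            parent[i] = cand[np.argmin(Dg[i, cand])]
    # follow links to roots
    mode_root = np.full(m, -1, dtype=int)
    for i in range(m):
        j = i
        seen = []
        while mode_root[j] < 0 and parent[j] != j:
            seen.append(j)
            j = parent[j]
        root = mode_root[j] if mode_root[j] >= 0 else j
        for s in seen + ([j] if mode_root[j] < 0 else []):
            mode_root[s] = root
    roots = np.unique(mode_root)
    relabel = {r: k for k, r in enumerate(roots)}
    mode_of_grid = np.array([relabel[r] for r in mode_root])
    return parent, mode_of_grid


def assign_frames(traj, grid, mode_of_grid, D=None) -> np.ndarray:
    """Give every frame the mode of its nearest grid point (periodic metric,
    ties to the lowest grid index)."""
    x = _as_angle_array(traj)
    grid = np.asarray(grid, dtype=int)
    if D is not None:
        Dv = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
        cols = Dv[:, grid]
    else:
        from .angles import dissimilarity_rows
        cols = dissimilarity_rows(x, x[grid]).T
    nearest = np.argmin(cols, axis=1)
    return np.asarray(mode_of_grid)[nearest]


# ---------------------------------------------------------------------------
# Covariance diagnostics
# ---------------------------------------------------------------------------

def circular_mean(angles: np.ndarray) -> np.ndarray:
    """Per-coordinate circular mean of an (n, M) angle block."""
    return np.arctan2(np.sin(angles).mean(axis=0), np.cos(angles).mean(axis=0))


def effective_dimension(eigenvalues) -> float:
    """exp of the Shannon entropy of the normalized eigenvalue spectrum.

    Equals the number of non-zero eigenvalues when the spectrum is flat and
    1 when a single direction carries all the variance.
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("spectrum has no positive eigenvalues")
    eta = lam / total
    nz = eta > 0
    return float(np.exp(-np.sum(eta[nz] * np.log(eta[nz]))))


def cluster_covariance(angles_block: np.ndarray) -> tuple[np.ndarray, bool]:
    """Circular-mean-centered minimal-image covariance of one cluster.

    Returns ``(covariance, wide_flag)``; the flag is set when any residual
    exceeds pi/2, i.e. the cluster is too spread for the tangent-space
    covariance to be trustworthy.
    """
    mu = circular_mean(angles_block)
    resid = periodic_difference(angles_block, mu[None, :])
    wide = bool(np.any(np.abs(resid) > np.pi / 2))
    C = (resid.T @ resid) / resid.shape[0]
    return C, wide


def cluster_stats(traj, mode_of_frame) -> ClusterStats:
    """Covariance-spectrum diagnostics for every cluster.

    Clusters with fewer than 2 frames get NaN statistics and are flagged.
    The determinant column is scaled so the largest-determinant cluster
    reads exactly 1 (computed via log-determinants to avoid underflow in
    high dimension).
    """
    x = _as_angle_array(traj)
    labels_all = np.asarray(mode_of_frame)
    labels = np.unique(labels_all)
    counts, spectra, logdets, top2, effd, flagged = [], [], [], [], [], []
    for c in labels:
        block = x[labels_all == c]
        counts.append(block.shape[0])
        if block.shape[0] < 2:
            spectra.append(np.full(x.shape[1], np.nan))
            logdets.append(-np.inf)
            top2.append(np.nan)
            effd.append(np.nan)
            flagged.append(True)
            continue
        C, wide = cluster_covariance(block)
        lam = np.sort(np.clip(np.linalg.eigvalsh(C), 0.0, None))[::-1]
        spectra.append(lam)
        with np.errstate(divide="ignore"):
            logdets.append(float(np.sum(np.log(lam))) if np.all(lam > 0) else -np.inf)
        top2.append(float(lam[:2].sum() / lam.sum()))
        effd.append(effective_dimension(lam))
        flagged.append(wide or block.shape[0] < x.shape[1] + 1)
    logdets = np.asarray(logdets)
    finite = np.isfinite(logdets)
    if np.any(finite):
        scaled = np.where(finite, np.exp(logdets - logdets[finite].max()), 0.0)
    else:
        scaled = np.full(len(labels), np.nan)
    return ClusterStats(
        labels=labels,
        counts=np.asarray(counts),
        eigenvalues=spectra,
        scaled_determinant=scaled,
        top2_fraction=np.asarray(top2),
        eff_dimension=np.asarray(effd),
        flagged=np.asarray(flagged),
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class ModeClustering(ClusterMixin, BaseEstimator):
    """Grid + KDE + Quick-Shift mode clustering of an angle trajectory.

    Parameters
    ----------
    grid_size : int or "auto"
        Number of grid frames (FPS-selected); "auto" uses min(N, 2000).
    bandwidth : float or None
        Wrapped-Gaussian KDE width in radians; None applies the default rule
        (half the median nearest-neighbor distance among grid points).
    lambda_cut : float or None
        Quick-Shift stopping distance; None uses 5 * bandwidth (comfortably
        above the tail spacing of the farthest-point grid, far below
        inter-basin separations).
    random_state : seed for the FPS start frame.

    Attributes
    ----------
    labels_ : mode label of every frame.
    model_ : the full :class:`ClusterModel`.
    n_modes_ : number of density modes found.
    """

    def __init__(self, grid_size="auto", bandwidth: float | None = None,
                 lambda_cut: float | None = None, random_state: int = 0):
        self.grid_size = grid_size
        self.bandwidth = bandwidth
        self.lambda_cut = lambda_cut
        self.random_state = random_state

    def fit(self, X, y=None):
        x = _as_angle_array(X)
        n = x.shape[0]
        m = min(n, 2000) if self.grid_size == "auto" else int(self.grid_size)
        D = pairwise_dissimilarity(x)
        grid = build_grid(D, m, seed=self.random_state)
        Dg = D.values[np.ix_(grid, grid)]
        h = self.bandwidth if self.bandwidth is not None else default_bandwidth(Dg)
        lam = self.lambda_cut if self.lambda_cut is not None else 5.0 * h
        dens = kde_on_grid(x, grid, h)
        parent, mode_of_grid = quick_shift(grid, dens, Dg, lam)
        mode_of_frame = assign_frames(x, grid, mode_of_grid, D)
        self.model_ = ClusterModel(grid, dens, parent, mode_of_grid,
                                   mode_of_frame, h, lam)
        self.labels_ = mode_of_frame
        self.bandwidth_ = h
        self.lambda_cut_ = lam
        self.n_modes_ = self.model_.n_modes
        return self

    def fit_predict(self, X, y=None):
        self.fit(X, y)
        return self.labels_


# ---------------------------------------------------------------------------
# Bootstrap significance of modes
# ---------------------------------------------------------------------------

def bootstrap_hierarchy(traj, reference_labels, n_boot: int = 41, seed: int = 0,
                        grid_size="auto", bandwidth=None,
                        lambda_cut=None) -> ClusterHierarchy:
    """Bootstrap merge distances between reference clusters.

    For each of ``n_boot`` resamples (frames drawn with replacement) the
    trajectory is reclustered with identical settings.  For a reference
    cluster c, the *majority mode* is the bootstrap mode most of c's
    resampled frames land in; clusters i and j merge in a replicate when
    their majority modes coincide.  ``merge_distance = 1 - merges / n_valid``
    where a replicate is valid for a pair only if both clusters received at
    least one resampled frame.  An average-linkage dendrogram is built on
    the distances.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = _as_angle_array(traj)
    if isinstance(reference_labels, ClusterModel):
        reference_labels = reference_labels.mode_of_frame
    ref = np.asarray(reference_labels)
    clusters = np.unique(ref)
    k = clusters.size
    merge_counts = np.zeros((k, k))
    valid_counts = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, x.shape[0], size=x.shape[0])
        sub_seed = int(rng.integers(2 ** 31))
        est = ModeClustering(grid_size=grid_size, bandwidth=bandwidth,
                             lambda_cut=lambda_cut, random_state=sub_seed)
        boot_labels = est.fit_predict(x[idx])
        ref_in_boot = ref[idx]
        majority = {}
        for c_i, c in enumerate(clusters):
            sel = boot_labels[ref_in_boot == c]
            if sel.size == 0:
                majority[c_i] = None
            else:
                majority[c_i] = int(np.bincount(sel).argmax())
        for a in range(k):
            for b in range(a + 1, k):
                if majority[a] is None or majority[b] is None:
                    continue
                valid_counts[a, b] += 1
                if majority[a] == majority[b]:
                    merge_counts[a, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(valid_counts > 0, merge_counts / valid_counts, 0.0)
    dist = 1.0 - freq
    dist = np.minimum(dist, dist.T)
    np.fill_diagonal(dist, 0.0)
    if k >= 2:
        condensed = dist[np.triu_indices(k, k=1)]
        linkage = sch.linkage(condensed, method="average")
    else:
        linkage = np.zeros((0, 4))
    return ClusterHierarchy(merge_distance=dist, linkage=linkage,
                            cluster_labels=clusters)


def majority_map(found_labels, reference_labels) -> dict:
    """Map each found cluster label to the reference label carried by the
    majority of its members (ties to the lowest reference label)."""
    found = np.asarray(found_labels)
    ref = np.asarray(reference_labels)
    return {int(c): int(np.bincount(ref[found == c]).argmax())
            for c in np.unique(found)}


def cut_macroclusters(hierarchy: ClusterHierarchy, threshold: float) -> np.ndarray:
    """Macro-cluster label per reference cluster: connected components of
    the dendrogram at linkage distance <= threshold, labels contiguous
    from 0 in order of first appearance."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    k = hierarchy.merge_distance.shape[0]
    if k == 1 or hierarchy.linkage.shape[0] == 0:
        return np.zeros(k, dtype=int)
    raw = sch.fcluster(hierarchy.linkage, t=threshold, criterion="distance")
    out = np.empty(k, dtype=int)
    seen = {}
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen)
        out[i] = seen[r]
    return out
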