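"""Projection fidelity diagnostics.

For an ideal projection the distance r_ij between two projected frames
equals the dissimilarity R_ij between the frames themselves, and the joint
density

    P(D, d) = 1 / (N(N-1)/2) * sum_{i<j} delta(R_ij - D) delta(r_ij - d)

has all its mass on the diagonal D = d.  Realized as a normalized 2-D
histogram over all unordered pairs, this density shows at a glance whether a
method systematically contracts pairs (all mass below the diagonal, as
linear projections must), stretches them, or scatters both ways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import DissimilarityMatrix
from .embed import Projection, _euclidean_distances


@dataclass
class JointHistogram:
    """Normalized joint density of (dissimilarity, projected distance) pairs."""

    D_edges: np.ndarray
    d_edges: np.ndarray
    density: np.ndarray
    n_pairs: int

    def integral(self) -> float:
        dD = np.diff(self.D_edges)
        dd = np.diff(self.d_edges)
        return float(np.sum(self.density * np.outer(dD, dd)))


def _pair_values(R, proj):
    Rv = R.values if isinstance(R, DissimilarityMatrix) else np.asarray(R, float)
    coords = proj.coords if isinstance(proj, Projection) else np.asarray(proj, float)
    n = Rv.shape[0]
    if coords.shape[0] != n:
        raise ValueError("dissimilarity matrix and projection refer to different N")
    if n < 2:
        raise ValueError("need at least 2 frames")
    iu = np.triu_indices(n, k=1)
    r = _euclidean_distances(coords)
    return Rv[iu], r[iu]


def joint_distance_histogram(R, proj, nbins_D: int = 100,
                             nbins_d: int = 100) -> JointHistogram:
    """Histogram estimate of P(D, d) over all unordered frame pairs.

    Bin ranges default to ``[0, max R] x [0, max(r, R)]`` so the D = d
    diagonal always lies inside the histogram; the density integrates to 1.
    """
    Rp, rp = _pair_values(R, proj)
    D_max = float(Rp.max())
    d_max = float(max(rp.max(), D_max))
    D_edges = np.linspace(0.0, D_max if D_max > 0 else 1.0, nbins_D + 1)
    d_edges = np.linspace(0.0, d_max if d_max > 0 else 1.0, nbins_d + 1)
    counts, _, _ = np.histogram2d(Rp, rp, bins=[D_edges, d_edges])
    n_pairs = Rp.size
    area = np.outer(np.diff(D_edges), np.diff(d_edges))
    density = counts / (n_pairs * area)
    return JointHistogram(D_edges, d_edges, density, n_pairs)


def contraction_fraction(R, proj) -> float:
    """Fraction of unordered pairs projected strictly closer than their
    dissimilarity (r_ij < R_ij)."""
    Rp, rp = _pair_values(R, proj)
    return float(np.mean(rp < Rp))


def pair_fractions(R, proj) -> dict:
    """Contracted / stretched / exactly-tied pair fractions (sum to 1)."""
    Rp, rp = _pair_values(R, proj)
    contracted = float(np.mean(rp < Rp))
    stretched = float(np.mean(rp > Rp))
    return {
        "contracted": contracted,
        "stretched": stretched,
        "tied": 1.0 - contracted - stretched,
    }
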