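"""Landmark selection (random / FPS / well-tempered FPS) and Voronoi weights.

Sketch-map and the sparse-grid stage of the mode clustering both operate on a
subset of landmark frames.  Three selection strategies are provided:

* ``random`` — uniform sampling without replacement;
* ``fps`` — farthest point sampling: greedily add the frame that maximizes its
  minimal distance to the landmarks chosen so far (spreads landmarks over the
  whole sampled region, including rarely-visited ones);
* ``wtfps`` — well-tempered FPS: a stochastic interpolation between FPS and
  density-weighted random sampling.  At every step each candidate frame i is
  assigned probability proportional to d_i^(2/gamma), where d_i is its minimal
  distance to the current landmark set.  gamma -> 0 recovers the deterministic
  argmax (plain FPS); large gamma approaches uniform sampling over the
  remaining frames.  Sampling is realized with the Gumbel-max trick on the
  logits (2/gamma) * log d_i, which is numerically exact for arbitrarily small
  gamma.

Voronoi weights count, for each landmark, the number of trajectory frames
whose nearest landmark it is, so the weights always sum to N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import DissimilarityMatrix


@dataclass
class LandmarkSet:
    """An ordered selection of landmark frames with optional Voronoi weights."""

    indices: np.ndarray
    weights: np.ndarray = None
    method_tag: str = "fps"
    seed: int | None = None
    gamma: float | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1 or self.indices.size == 0:
            raise ValueError("landmark indices must be a non-empty 1-D sequence")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("landmark indices must be distinct")
        if np.any(self.indices < 0):
            raise ValueError("landmark indices must be non-negative")
        if self.weights is None:
            self.weights = np.ones(self.indices.size)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.indices.shape:
            raise ValueError("weights must match indices in shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return self.indices.size


def _as_dissimilarity(D) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return DissimilarityMatrix(np.asarray(D, dtype=float)).values


def fps_select(D, n: int, start: int = 0) -> LandmarkSet:
    """Greedy farthest point sampling of ``n`` landmarks, starting from frame
    ``start``.  Deterministic; ties broken to the lowest frame index."""
    Dv = _as_dissimilarity(D)
    N = Dv.shape[0]
    if not 1 <= n <= N:
        raise ValueError(f"landmark count n={n} must satisfy 1 <= n <= N={N}")
    if not 0 <= start < N:
        raise ValueError(f"start index {start} out of range")
    chosen = [start]
    dmin = Dv[start].copy()
    for _ in range(1, n):
        nxt = int(np.argmax(dmin))  # argmax ties -> lowest index
        chosen.append(nxt)
        np.minimum(dmin, Dv[nxt], out=dmin)
    return LandmarkSet(np.array(chosen), method_tag="fps")


def wtfps_select(D, n: int, gamma: float, seed: int, start: int = 0) -> LandmarkSet:
    """Well-tempered farthest point sampling.

    The next landmark is drawn with probability proportional to d_i^(2/gamma)
    over frames not yet selected (d_i = minimal distance to the current set);
    frames at zero distance are excluded.  Reproducible given ``seed``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    Dv = _as_dissimilarity(D)
    N = Dv.shape[0]
    if not 1 <= n <= N:
        raise ValueError(f"landmark count n={n} must satisfy 1 <= n <= N={N}")
    rng = np.random.default_rng(seed)
    chosen = [start]
    dmin = Dv[start].copy()
    for _ in range(1, n):
        with np.errstate(divide="ignore"):
            logits = (2.0 / gamma) * np.log(dmin)  # d=0 -> -inf (excluded)
        gumbel = rng.gumbel(size=N)
        score = np.where(np.isneginf(logits), -np.inf, logits + gumbel)
        if not np.any(np.isfinite(score)):
            raise ValueError("all remaining frames coincide with chosen landmarks")
        nxt = int(np.argmax(score))
        chosen.append(nxt)
        np.minimum(dmin, Dv[nxt], out=dmin)
    return LandmarkSet(np.array(chosen), method_tag="wtfps", seed=seed, gamma=gamma)


def random_select(N_or_D, n: int, seed: int) -> LandmarkSet:
    """Uniform landmark sampling without replacement."""
    if isinstance(N_or_D, (int, np.integer)):
        N = int(N_or_D)
    else:
        N = _as_dissimilarity(N_or_D).shape[0]
    if not 1 <= n <= N:
        raise ValueError(f"landmark count n={n} must satisfy 1 <= n <= N={N}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(N, size=n, replace=False)
    return LandmarkSet(idx, method_tag="random", seed=seed)


def nearest_landmark(D, landmarks: LandmarkSet) -> np.ndarray:
    """Index (into ``landmarks.indices``) of each frame's nearest landmark.

    Ties are broken to the landmark with the lowest *frame* index.
    """
    Dv = _as_dissimilarity(D)
    order = np.argsort(landmarks.indices, kind="stable")
    cols = Dv[:, landmarks.indices[order]]
    nearest_sorted = np.argmin(cols, axis=1)  # first minimum -> lowest frame idx
    return order[nearest_sorted]


def voronoi_weights(D, landmarks: LandmarkSet) -> LandmarkSet:
    """Fill landmark weights with Voronoi populations (weights sum to N)."""
    Dv = _as_dissimilarity(D)
    if landmarks.n == 0:
        raise ValueError("empty landmark set")
    if np.any(landmarks.indices >= Dv.shape[0]):
        raise ValueError("landmark indices exceed the frame count of D")
    assign = nearest_landmark(Dv, landmarks)
    weights = np.bincount(assign, minlength=landmarks.n).astype(float)
    return LandmarkSet(
        landmarks.indices.copy(),
        weights=weights,
        method_tag=landmarks.method_tag,
        seed=landmarks.seed,
        gamma=landmarks.gamma,
    )
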