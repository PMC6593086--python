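"""Sketch-map: sigmoid-filtered multidimensional scaling over landmarks.

Sketch-map reproduces only a band of length scales around a switching
distance sigma.  Both the high-dimensional dissimilarities R and the
low-dimensional distances r are passed through a sigmoid

    F_{sigma,p,q}(r) = 1 - (1 + (2^(p/q) - 1) (r/sigma)^p)^(-q/p),

with F(0) = 0 and F(sigma) = 1/2 for every exponent pair, and the weighted
stress

    chi = sum_{i<j} w_i w_j [F_{sigma,A,B}(R_ij) - F_{sigma,a,b}(r_ij)]^2
          / sum_{i<j} w_i w_j

is minimized over the projected landmark coordinates.  Distances much
shorter or much longer than sigma saturate the sigmoid, so the optimizer
concentrates on getting pair separations near sigma right — short-range
thermal noise and long-range "distance on the torus is meaningless" regimes
are both discounted.

Remaining frames are placed by the out-of-sample procedure: each frame
minimizes its own single-point stress against the fixed landmark
projections, located by a coarse grid search over the landmark bounding box
followed by local refinement (the single-point stress is multimodal, so
pure local descent from one start is unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .angles import _as_angle_array, dissimilarity_rows, pairwise_dissimilarity
from .embed import Projection, _euclidean_distances, classical_mds
from .landmarks import LandmarkSet, voronoi_weights, wtfps_select


@dataclass
class SketchMapParams:
    """Switching distance and sigmoid exponents.

    ``sigma`` sets the length scale whose neighborhood of distances is
    reproduced; ``(A, B)`` shape the high-dimensional sigmoid and ``(a, b)``
    the low-dimensional one.  Defaults follow the reference analysis of the
    32-dihedral peptide trajectory: sigma=6, A=8, B=8, a=2, b=8.
    """

    sigma: float = 6.0
    A: float = 8.0
    B: float = 8.0
    a: float = 2.0
    b: float = 8.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("A", "B", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exponent {name} must be > 0")


def sigmoid_transform(r, sigma: float, p: float, q: float):
    """The sketch-map switching function F_{sigma,p,q}; maps [0, inf) -> [0, 1)."""
    if sigma <= 0 or p <= 0 or q <= 0:
        raise ValueError("sigma, p, q must all be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    c = 2.0 ** (p / q) - 1.0
    val = 1.0 - (1.0 + c * (r / sigma) ** p) ** (-q / p)
    return float(val) if val.ndim == 0 else val


def _sigmoid_and_grad(r: np.ndarray, sigma: float, p: float, q: float):
    """F(r) and dF/dr, vectorized; dF/dr at r=0 is taken as 0 for p > 1."""
    c = 2.0 ** (p / q) - 1.0
    u = (r / sigma) ** p
    base = 1.0 + c * u
    F = 1.0 - base ** (-q / p)
    with np.errstate(divide="ignore", invalid="ignore"):
        dF = q * c * (r / sigma) ** (p - 1.0) / sigma * base ** (-q / p - 1.0)
    dF = np.where(np.isfinite(dF), dF, 0.0)
    return F, dF


def landmark_stress(R, r, w, params: SketchMapParams) -> float:
    """Weighted sketch-map stress between landmark dissimilarities ``R`` and
    projected distances ``r`` (both n x n), normalized by sum_{i<j} w_i w_j."""
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    if R.shape != r.shape:
        raise ValueError("R and r must have the same shape")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    ww = np.outer(w, w)[iu]
    norm = ww.sum()
    if norm <= 0:
        raise ValueError("all pair weights vanish: cannot normalize the stress")
    FH = sigmoid_transform(R[iu], params.sigma, params.A, params.B)
    FL = sigmoid_transform(r[iu], params.sigma, params.a, params.b)
    return float(np.sum(ww * (FH - FL) ** 2) / norm)


def fit_landmarks(D_landmarks, weights, params: SketchMapParams, d: int = 2,
                  seed: int = 0, max_iter: int = 2000, tol: float = 1e-9,
                  init: str = "classical") -> Projection:
    """Optimize landmark projections under the sketch-map stress.

    Initializes from classical MDS of the F-transformed dissimilarities
    (deterministic) and refines with L-BFGS using the analytic gradient.
    """
    R = np.asarray(D_landmarks, dtype=float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least 2 landmarks")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    ww = np.outer(w, w)
    np.fill_diagonal(ww, 0.0)
    norm = ww.sum() / 2.0
    if norm <= 0:
        raise ValueError("all pair weights vanish: cannot normalize the stress")
    FH = sigmoid_transform(R, params.sigma, params.A, params.B)
    np.fill_diagonal(FH, 0.0)

    if init == "classical":
        x0, _ = classical_mds(FH * params.sigma, d)
    elif init == "random":
        rng = np.random.default_rng(seed)
        x0 = rng.standard_normal((n, d)) * params.sigma
    else:
        raise ValueError(f"unknown init {init!r}")

    def fun(flat):
        x = flat.reshape(n, d)
        r = _euclidean_distances(x)
        FL, dFL = _sigmoid_and_grad(r, params.sigma, params.a, params.b)
        np.fill_diagonal(FL, 0.0)
        diff = FH - FL
        chi = np.sum(ww * diff ** 2) / (2.0 * norm)
        with np.errstate(divide="ignore", invalid="ignore"):
            coef = np.where(r > 0, -2.0 * ww * diff * dFL / r, 0.0)
        grad = (x * coef.sum(axis=1)[:, None] - coef @ x) / norm
        return chi, grad.ravel()

    chi0 = fun(x0.ravel())[0]
    trace = [chi0]

    def cb(flat):
        trace.append(fun(flat)[0])

    res = scipy.optimize.minimize(
        fun, x0.ravel(), jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12},
    )
    coords = res.x.reshape(n, d)
    final = fun(res.x)[0]
    if final > chi0:
        coords, final = x0, chi0
    trace.append(final)
    return Projection(
        coords, "sketch-map",
        {"sigma": params.sigma, "A": params.A, "B": params.B,
         "a": params.a, "b": params.b, "d": d, "seed": seed, "stress": final},
        loss_trace=np.minimum.accumulate(np.asarray(trace)),
    )


def _single_point_stress(x, proj_coords, w, FH_row, params: SketchMapParams):
    """Stress of one out-of-sample point at position(s) ``x`` (…, d)."""
    x = np.asarray(x, dtype=float)
    diff = x[..., None, :] - proj_coords[None, :, :] if x.ndim > 1 else x - proj_coords
    r = np.sqrt(np.sum(diff ** 2, axis=-1))
    FL = sigmoid_transform(r, params.sigma, params.a, params.b)
    return np.sum(w * (FH_row - FL) ** 2, axis=-1)


def out_of_sample(D_to_landmarks, landmark_proj, weights, params: SketchMapParams,
                  grid_points: int | None = None, margin: float = 0.2) -> np.ndarray:
    """Project frames onto a fitted sketch-map.

    Parameters
    ----------
    D_to_landmarks : (n_frames, n_landmarks) or (n_landmarks,) array
        Periodic dissimilarities from each frame to every landmark.
    landmark_proj : Projection or (n_landmarks, d) array
        Fitted landmark coordinates.
    weights : (n_landmarks,) Voronoi weights.
    grid_points : grid resolution per dimension for the coarse search
        (default: 50 for d = 2, scaled so the grid stays near 2500 points
        for other d).

    Each frame's single-point stress is scanned on a regular grid over the
    landmark bounding box expanded by ``margin``, and the best grid cell is
    polished with Nelder-Mead.  Returns (n_frames, d) coordinates.
    """
    coords = landmark_proj.coords if isinstance(landmark_proj, Projection) else np.asarray(landmark_proj, float)
    if coords.size == 0:
        raise ValueError("empty landmark projection")
    R = np.atleast_2d(np.asarray(D_to_landmarks, dtype=float))
    if R.shape[1] != coords.shape[0]:
        raise ValueError("dissimilarity row length must equal the landmark count")
    w = np.ones(coords.shape[0]) if weights is None else np.asarray(weights, float)
    d = coords.shape[1]
    if grid_points is None:
        grid_points = max(4, int(round(2500 ** (1.0 / d))))
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - margin * span
    hi = hi + margin * span
    axes = [np.linspace(lo[j], hi[j], grid_points) for j in range(d)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)

    FH = sigmoid_transform(R, params.sigma, params.A, params.B)
    out = np.empty((R.shape[0], d))
    # grid distances to landmarks are shared across frames
    grid_r = np.sqrt(
        np.maximum(
            ((mesh ** 2).sum(1)[:, None] + (coords ** 2).sum(1)[None, :]
             - 2.0 * mesh @ coords.T),
            0.0,
        )
    )
    FL_grid = sigmoid_transform(grid_r, params.sigma, params.a, params.b)
    for i in range(R.shape[0]):
        vals = ((FL_grid - FH[i][None, :]) ** 2 * w[None, :]).sum(axis=1)
        x0 = mesh[int(np.argmin(vals))]
        res = scipy.optimize.minimize(
            _single_point_stress, x0, args=(coords, w, FH[i], params),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400},
        )
        out[i] = res.x if res.fun <= vals.min() else x0
    return out


class SketchMap(TransformerMixin, BaseEstimator):
    """Full sketch-map pipeline as a transformer.

    ``fit`` selects landmarks by well-tempered farthest point sampling,
    attaches Voronoi weights, and optimizes the landmark projections under
    the sigmoid-filtered stress; ``transform`` places arbitrary frames with
    the out-of-sample procedure.

    Parameters mirror the reference peptide analysis: 1000 landmarks chosen
    with tempering parameter ``landmark_gamma = 0.1``, sigma=6, A=8, B=8,
    a=2, b=8.

    Attributes
    ----------
    landmarks_ : LandmarkSet with Voronoi weights.
    landmark_projection_ : Projection of the landmark frames.
    embedding_ : (N, d) projection of all training frames.
    stress_ : final landmark stress.
    """

    def __init__(self, n_landmarks: int = 1000, landmark_gamma: float = 0.1,
                 sigma: float = 6.0, A: float = 8.0, B: float = 8.0,
                 a: float = 2.0, b: float = 8.0, n_components: int = 2,
                 random_state: int = 0, max_iter: int = 2000, tol: float = 1e-9):
        self.n_landmarks = n_landmarks
        self.landmark_gamma = landmark_gamma
        self.sigma = sigma
        self.A = A
        self.B = B
        self.a = a
        self.b = b
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def _params(self) -> SketchMapParams:
        return SketchMapParams(self.sigma, self.A, self.B, self.a, self.b)

    def fit(self, X, y=None):
        x = _as_angle_array(X)
        self._train_angles = x
        D = pairwise_dissimilarity(x)
        n_land = min(self.n_landmarks, x.shape[0])
        lset = wtfps_select(D, n_land, self.landmark_gamma, self.random_state)
        lset = voronoi_weights(D, lset)
        R_land = D.values[np.ix_(lset.indices, lset.indices)]
        proj = fit_landmarks(R_land, lset.weights, self._params(),
                             d=self.n_components, seed=self.random_state,
                             max_iter=self.max_iter, tol=self.tol)
        self.landmarks_ = lset
        self.landmark_projection_ = proj
        self.stress_ = proj.params["stress"]
        self.embedding_ = self.transform(x)
        return self

    def transform(self, X):
        x = _as_angle_array(X)
        rows = dissimilarity_rows(x, self._train_angles[self.landmarks_.indices])
        return out_of_sample(rows, self.landmark_projection_,
                             self.landmarks_.weights, self._params())

    def fit_transform(self, X, y=None):
        self.fit(X, y)
        return self.embedding_
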