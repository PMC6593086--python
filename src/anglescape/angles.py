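"""Dihedral-angle featurization and periodic (minimal-image) geometry.

Trajectory frames are represented as points on the M-torus: each frame is a
vector of M backbone dihedral angles in radians, stored in ``[-pi, pi)``.
All downstream distances honor the periodicity of these coordinates: the
dissimilarity between two frames is the Euclidean norm of the per-angle
minimal-image differences,

    R_ij = sqrt( sum_k wrap(theta_k^(i) - theta_k^(j))^2 ),

which is the natural flat metric on the torus.  The sin/cos embedding maps
each angle onto the unit circle and is the representation used by
periodicity-aware PCA (dPCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

try:  # JIT fast path for the O(N^2 M) distance kernels
    import numba as _numba

    @_numba.njit(cache=False)
    def _pairwise_kernel(x):
        n, m = x.shape
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                acc = 0.0
                for k in range(m):
                    d = abs(x[i, k] - x[j, k])
                    if d > np.pi:
                        d = TWO_PI - d
                    acc += d * d
                r = np.sqrt(acc)
                out[i, j] = r
                out[j, i] = r
        return out

except ImportError:  # pragma: no cover - numba is a declared dependency
    _pairwise_kernel = None


def wrap_angles(a: np.ndarray | float) -> np.ndarray:
    """Wrap angles into the canonical domain ``[-pi, pi)``."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass
class AngleTrajectory:
    """N frames x M dihedral angles (radians) on the M-torus.

    Parameters
    ----------
    angles : (N, M) array
        Dihedral angles in radians; every entry must lie in ``[-pi, pi)``.
    frame_ids : sequence of N identifiers, optional
        Defaults to ``0..N-1``.
    angle_names : sequence of M labels, optional
        Defaults to ``angle_0 .. angle_{M-1}``.
    """

    angles: np.ndarray
    frame_ids: list = field(default=None)
    angle_names: list = field(default=None)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2:
            raise ValueError("angles must be a 2-D (N, M) array")
        n, m = self.angles.shape
        if n < 1 or m < 1:
            raise ValueError("need N >= 1 frames and M >= 1 angles")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite values")
        if np.any(self.angles < -np.pi) or np.any(self.angles >= np.pi):
            raise ValueError("angles must lie in [-pi, pi); use wrap_angles() first")
        if self.frame_ids is None:
            self.frame_ids = list(range(n))
        if self.angle_names is None:
            self.angle_names = [f"angle_{k}" for k in range(m)]
        if len(self.frame_ids) != n:
            raise ValueError("frame_ids length does not match frame count")
        if len(self.angle_names) != m:
            raise ValueError("angle_names length does not match angle count")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles.shape[1]


@dataclass
class DissimilarityMatrix:
    """Symmetric N x N matrix of periodic Euclidean dissimilarities."""

    values: np.ndarray
    metric_tag: str = "periodic-euclidean"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _as_angle_array(traj) -> np.ndarray:
    if isinstance(traj, AngleTrajectory):
        return traj.angles
    a = np.asarray(traj, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected an (N, M) angle array or AngleTrajectory")
    return a


def periodic_difference(a, b):
    """Minimal-image difference a - b on the circle, in ``(-pi, pi]``.

    The tie at ``|a - b| = pi`` is broken to ``+pi`` so the result is
    deterministic.  Works elementwise on arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("periodic_difference requires finite inputs")
    d = np.mod((a - b) + np.pi, TWO_PI) - np.pi  # [-pi, pi)
    d = np.where(d == -np.pi, np.pi, d)
    if d.ndim == 0:
        return float(d)
    return d


def pairwise_dissimilarity(traj) -> DissimilarityMatrix:
    """Full N x N periodic Euclidean dissimilarity matrix.

    Accumulates squared minimal-image differences one coordinate at a time,
    so peak memory stays at a few N x N blocks regardless of M.
    """
    x = _as_angle_array(traj)
    n, m = x.shape
    if _pairwise_kernel is not None and n * m > 50_000:
        out = _pairwise_kernel(np.ascontiguousarray(x))
    else:
        acc = np.zeros((n, n))
        buf = np.empty((n, n))
        alt = np.empty((n, n))
        for k in range(m):
            np.subtract(x[:, k][:, None], x[None, :, k], out=buf)
            np.abs(buf, out=buf)
            np.subtract(TWO_PI, buf, out=alt)
            np.minimum(buf, alt, out=buf)
            buf *= buf
            acc += buf
        out = np.sqrt(acc)
    # exact symmetry / zero diagonal against rounding
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return DissimilarityMatrix(out)


def dissimilarity_rows(x_rows, x_all) -> np.ndarray:
    """Periodic dissimilarities from each row of ``x_rows`` to every row of
    ``x_all`` (shape ``(len(x_rows), len(x_all))``), without forming N x N."""
    a = np.atleast_2d(np.asarray(x_rows, dtype=float))
    b = _as_angle_array(x_all)
    diff = np.abs(a[:, None, :] - b[None, :, :])
    np.minimum(diff, TWO_PI - diff, out=diff)
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def sincos_embed(traj) -> np.ndarray:
    """Map each angle onto the unit circle: row i is
    ``(cos t_i1, sin t_i1, ..., cos t_iM, sin t_iM)`` (shape ``(N, 2M)``)."""
    x = _as_angle_array(traj)
    n, m = x.shape
    out = np.empty((n, 2 * m))
    out[:, 0::2] = np.cos(x)
    out[:, 1::2] = np.sin(x)
    return out


# ---------------------------------------------------------------------------
# Dihedral extraction from atomic coordinates
# ---------------------------------------------------------------------------

def dihedral_from_points(p0, p1, p2, p3) -> float:
    """Torsion angle of the bonded quadruple p0-p1-p2-p3 in ``[-pi, pi)``.

    IUPAC right-handed sign convention: the eclipsed (cis) arrangement is 0,
    the anti (trans) arrangement is +/-pi, and rotating p3 by +90 degrees
    about the p1->p2 axis (right-hand rule) from cis gives +pi/2.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear atom triple in torsion")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = np.arctan2(y, x)
    return float(wrap_angles(ang))


def dihedrals_from_coordinates(pdb_path, torsions, angle_names=None) -> AngleTrajectory:
    """Compute a torsion-angle trajectory from a (possibly multi-MODEL) PDB file.

    Parameters
    ----------
    pdb_path : str or Path
        PDB file; each MODEL record is one trajectory frame.
    torsions : list of 4-tuples ``(chain_id, residue_number, atom_name)``
        Each torsion is defined by four named atoms, all of which must be
        present in every model.
    angle_names : optional list of labels, one per torsion.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(pdb_path))
    models = list(structure)
    if not models:
        raise ValueError(f"no MODEL records found in {pdb_path}")

    def atom_coord(model, spec, torsion_index):
        chain_id, resseq, atom_name = spec
        try:
            return np.array(model[chain_id][(" ", resseq, " ")][atom_name].coord, float)
        except KeyError:
            raise ValueError(
                f"torsion {torsion_index}: atom {atom_name} of residue "
                f"{chain_id}:{resseq} missing from model {model.id}"
            ) from None

    rows = []
    for model in models:
        row = []
        for t_idx, quad in enumerate(torsions):
            if len(quad) != 4:
                raise ValueError("each torsion needs exactly 4 atom specifications")
            pts = [atom_coord(model, spec, t_idx) for spec in quad]
            row.append(dihedral_from_points(*pts))
        rows.append(row)
    names = angle_names or [f"torsion_{k}" for k in range(len(torsions))]
    return AngleTrajectory(np.array(rows), angle_names=list(names))


def backbone_phi_psi_torsions(chain_id: str, residue_numbers) -> tuple[list, list]:
    """Standard phi/psi torsion quadruples for a run of consecutive residues.

    phi_i: C(i-1)-N(i)-CA(i)-C(i); psi_i: N(i)-CA(i)-C(i)-N(i+1).
    Returns ``(torsions, names)`` suitable for :func:`dihedrals_from_coordinates`.
    """
    residue_numbers = list(residue_numbers)
    torsions, names = [], []
    for i in residue_numbers:
        if i - 1 in residue_numbers:
            torsions.append(
                ((chain_id, i - 1, "C"), (chain_id, i, "N"),
                 (chain_id, i, "CA"), (chain_id, i, "C"))
            )
            names.append(f"phi_{i}")
        if i + 1 in residue_numbers:
            torsions.append(
                ((chain_id, i, "N"), (chain_id, i, "CA"),
                 (chain_id, i, "C"), (chain_id, i + 1, "N"))
            )
            names.append(f"psi_{i}")
    return torsions, names
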