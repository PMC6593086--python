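"""Plain-text serialization of trajectories, matrices, projections, landmarks.

Everything is delimited text (comma or whitespace) at full double precision
(``%.17g``), so a write/read round trip reproduces values to better than
1e-12 and outputs stay diffable and checksummable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .angles import AngleTrajectory, wrap_angles
from .embed import Projection
from .landmarks import LandmarkSet

_FMT = "%.17g"


class MatrixParseError(ValueError):
    """Raised when a delimited-text matrix file cannot be parsed."""


def write_matrix(path, matrix, header: list | None = None) -> None:
    """Write a 2-D matrix as whitespace-delimited text, optionally with a
    ``#``-prefixed header row of column names."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("refusing to write an empty or non-2D matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values")
    lines = []
    if header is not None:
        if len(header) != m.shape[1]:
            raise ValueError("header length must match column count")
        lines.append("# " + " ".join(str(h) for h in header))
    for row in m:
        lines.append(" ".join(_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list | None]:
    """Read a delimited-text matrix (comma or whitespace); returns
    ``(matrix, header_or_None)``.  Malformed lines raise
    :class:`MatrixParseError` naming the line number."""
    text = Path(path).read_text()
    rows, header, width = [], None, None
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if lineno == 1 or (header is None and not rows):
                header = s.lstrip("#").replace(",", " ").split()
            continue
        parts = s.replace(",", " ").split()
        try:
            row = [float(p) for p in parts]
        except ValueError:
            raise MatrixParseError(f"{path}: line {lineno}: non-numeric entry") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise MatrixParseError(
                f"{path}: line {lineno}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise MatrixParseError(f"{path}: no data rows found")
    return np.array(rows), header


def write_trajectory(path, traj: AngleTrajectory) -> None:
    write_matrix(path, traj.angles, header=traj.angle_names)


def read_trajectory(path, degrees: bool = False) -> AngleTrajectory:
    """Load an angle trajectory from delimited text; ``degrees=True``
    converts on read and wraps into [-pi, pi)."""
    m, header = read_matrix(path)
    if degrees:
        m = np.deg2rad(m)
    m = wrap_angles(m)
    return AngleTrajectory(m, angle_names=header)


def write_projection(path, proj: Projection) -> None:
    """Projection coordinates as text plus a JSON sidecar of metadata."""
    write_matrix(path, proj.coords)
    sidecar = {
        "method": proj.method_tag,
        "params": {k: _jsonable(v) for k, v in proj.params.items()},
    }
    if proj.loss_trace is not None:
        sidecar["final_loss"] = float(proj.loss_trace[-1])
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_projection(path) -> Projection:
    coords, _ = read_matrix(path)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Projection(coords, meta.get("method", "unknown"), meta.get("params", {}))


def write_landmarks(path, lset: LandmarkSet) -> None:
    """Two-column (index, weight) text plus a JSON sidecar (method, seed, gamma)."""
    data = np.column_stack([lset.indices.astype(float), lset.weights])
    write_matrix(path, data, header=["index", "weight"])
    sidecar = {"method": lset.method_tag, "seed": lset.seed, "gamma": lset.gamma}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_landmarks(path) -> LandmarkSet:
    data, _ = read_matrix(path)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return LandmarkSet(data[:, 0].astype(int), weights=data[:, 1],
                       method_tag=meta.get("method", "unknown"),
                       seed=meta.get("seed"), gamma=meta.get("gamma"))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
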