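"""Configuration-driven driver: simulate -> featurize -> project -> evaluate
-> cluster, with a checksummed manifest for bit-stable reruns.

A run is described by one YAML mapping (see :class:`RunConfig`).  Every
stage writes plain-text artifacts into the output directory and records a
SHA-256 checksum in ``manifest.json``; identical configuration and seeds
give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as asio
from .angles import AngleTrajectory, pairwise_dissimilarity
from .embed import (
    Projection,
    dpca_project,
    isomap_project,
    laplacian_eigenmaps_project,
    stress_minimize,
    tsne_project,
)
from .modecluster import ModeClustering, cluster_stats
from .projeval import joint_distance_histogram, pair_fractions
from .sketchmap import SketchMap
from .synth import reference_scenario, sample_torus_mixture

logger = logging.getLogger("anglescape")

#: methods and the per-method parameters a config may set
KNOWN_METHODS = {
    "dpca": set(),
    "dist_match": {"max_iter", "tol", "init"},
    "isomap": {"n_neighbors"},
    "laplacian_eigenmaps": {"n_neighbors", "kernel_gamma"},
    "tsne": {"perplexity", "n_iter", "learning_rate"},
    "sketch_map": {"n_landmarks", "landmark_gamma", "sigma", "A", "B", "a", "b",
                   "max_iter"},
}

#: hard cap on frames held in a dense dissimilarity matrix
MAX_FRAMES_DEFAULT = 30_000


@dataclass
class RunConfig:
    """Validated run description.

    Exactly one of ``scenario`` (synthetic mixture name) or ``input_path``
    (delimited-text angle trajectory) must be given.
    """

    output_dir: str
    scenario: str | None = None
    input_path: str | None = None
    n_frames: int = 1000
    seed: int = 0
    n_components: int = 2
    methods: dict = field(default_factory=lambda: {"dpca": {}})
    cluster: dict | None = field(default_factory=dict)
    max_frames: int = MAX_FRAMES_DEFAULT
    degrees: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text())
        if not isinstance(obj, dict):
            raise ConfigError(["config file must contain a YAML mapping"])
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(obj) - known
        errors = [f"unknown config key: {k}" for k in sorted(unknown)]
        cfg = cls(**{k: v for k, v in obj.items() if k in known})
        errors += cfg.validate()
        if errors:
            raise ConfigError(errors)
        return cfg

    def validate(self) -> list:
        """Collect every validation problem (empty list = valid)."""
        errors = []
        if (self.scenario is None) == (self.input_path is None):
            errors.append("exactly one of 'scenario' or 'input_path' is required")
        if self.scenario is not None and self.scenario not in (
                "two_funnels", "eleven_modes", "well_separated"):
            errors.append(f"unknown scenario {self.scenario!r}")
        if self.n_frames < 1:
            errors.append("n_frames must be >= 1")
        if self.n_frames > self.max_frames:
            errors.append(f"n_frames={self.n_frames} exceeds max_frames={self.max_frames}")
        if self.n_components < 1:
            errors.append("n_components must be >= 1")
        if not isinstance(self.methods, dict) or not self.methods:
            errors.append("methods must be a non-empty mapping")
        else:
            for name, params in self.methods.items():
                if name not in KNOWN_METHODS:
                    errors.append(f"unknown method {name!r}")
                    continue
                params = params or {}
                bad = set(params) - KNOWN_METHODS[name]
                for k in sorted(bad):
                    errors.append(f"method {name!r}: unknown parameter {k!r}")
                if name == "tsne":
                    perp = params.get("perplexity", 110.0)
                    if perp >= self.n_frames:
                        errors.append(
                            f"tsne perplexity {perp} must be < n_frames {self.n_frames}"
                        )
        return errors


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _project_one(name: str, params: dict, traj: AngleTrajectory, D,
                 d: int, seed: int) -> Projection:
    params = dict(params or {})
    if name == "dpca":
        return dpca_project(traj, d=d)
    if name == "dist_match":
        return stress_minimize(D, d=d, seed=seed, **params)
    if name == "isomap":
        return isomap_project(D, k=params.get("n_neighbors", 15), d=d)
    if name == "laplacian_eigenmaps":
        return laplacian_eigenmaps_project(
            D, k=params.get("n_neighbors", 15),
            gamma=params.get("kernel_gamma", 1.0), d=d)
    if name == "tsne":
        return tsne_project(D, perplexity=params.get("perplexity", 110.0), d=d,
                            seed=seed, iters=params.get("n_iter", 1000),
                            learning_rate=params.get("learning_rate", 200.0))
    if name == "sketch_map":
        est = SketchMap(n_components=d, random_state=seed, **params)
        est.fit(traj.angles)
        return Projection(est.embedding_, "sketch_map",
                          {**est.get_params(), "stress": est.stress_})
    raise ValueError(f"unknown method {name!r}")


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest (also written
    to ``<output_dir>/manifest.json``)."""
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: getattr(config, k) for k in (
            "scenario", "input_path", "n_frames", "seed", "n_components")},
        "methods": {k: (v or {}) for k, v in config.methods.items()},
        "artifacts": {},
        "stages": [],
        "errors": {},
    }

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)), "sha256": _sha256(path)}

    def stage(name):
        t0 = time.time()
        manifest["stages"].append({"name": name, "started": True})

        def done(**info):
            manifest["stages"][-1].update(wall_time_s=round(time.time() - t0, 3), **info)
        return done

    # --- simulate / load -------------------------------------------------
    done = stage("featurize")
    if config.scenario is not None:
        spec = reference_scenario(config.scenario, seed=config.seed)
        traj, labels = sample_torus_mixture(spec, config.n_frames, seed=config.seed)
        (out / "mixture_spec.json").write_text(spec.to_json())
        record("mixture_spec", out / "mixture_spec.json")
        asio.write_matrix(out / "planted_labels.txt", labels[:, None].astype(float))
        record("planted_labels", out / "planted_labels.txt")
    else:
        traj = asio.read_trajectory(config.input_path, degrees=config.degrees)
        if traj.n_frames > config.max_frames:
            raise ConfigError([f"input has {traj.n_frames} frames; cap is "
                               f"{config.max_frames}"])
    asio.write_trajectory(out / "trajectory.txt", traj)
    record("trajectory", out / "trajectory.txt")
    D = pairwise_dissimilarity(traj)
    logger.info("featurize: N=%d frames, M=%d angles", traj.n_frames, traj.n_angles)
    done(n_frames=traj.n_frames, n_angles=traj.n_angles)

    # --- project + evaluate ----------------------------------------------
    for name, params in config.methods.items():
        done = stage(f"project:{name}")
        try:
            proj = _project_one(name, params, traj, D, config.n_components,
                                config.seed)
        except Exception as exc:  # record and continue with other methods
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
            done(failed=True)
            continue
        ppath = out / f"projection_{name}.txt"
        asio.write_projection(ppath, proj)
        record(f"projection_{name}", ppath)
        record(f"projection_{name}_meta", Path(str(ppath) + ".json"))

        hist = joint_distance_histogram(D, proj)
        hpath = out / f"histogram_{name}.txt"
        asio.write_matrix(hpath, hist.density)
        record(f"histogram_{name}", hpath)
        frac = pair_fractions(D, proj)
        (out / f"fractions_{name}.json").write_text(
            json.dumps(frac, indent=2, sort_keys=True))
        record(f"fractions_{name}", out / f"fractions_{name}.json")
        logger.info("project %s: d=%d, contracted %.3f",
                    name, config.n_components, frac["contracted"])
        done(contracted=frac["contracted"])

    # --- cluster ----------------------------------------------------------
    if config.cluster is not None:
        done = stage("cluster")
        try:
            copts = dict(config.cluster or {})
            est = ModeClustering(
                grid_size=copts.get("grid_size", "auto"),
                bandwidth=copts.get("bandwidth"),
                lambda_cut=copts.get("lambda_cut"),
                random_state=config.seed,
            )
            est.fit(traj.angles)
            asio.write_matrix(out / "mode_labels.txt",
                              est.labels_[:, None].astype(float))
            record("mode_labels", out / "mode_labels.txt")
            stats = cluster_stats(traj, est.labels_)
            stats_rows = np.column_stack([
                stats.labels.astype(float), stats.counts.astype(float),
                stats.scaled_determinant, stats.top2_fraction,
                stats.eff_dimension])
            asio.write_matrix(out / "cluster_stats.txt", stats_rows,
                              header=["label", "count", "scaled_det",
                                      "top2_fraction", "eff_dimension"])
            record("cluster_stats", out / "cluster_stats.txt")
            logger.info("cluster: %d modes", est.n_modes_)
            done(n_modes=int(est.n_modes_))
        except Exception as exc:
            manifest["errors"]["cluster"] = f"{type(exc).__name__}: {exc}"
            done(failed=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def roundtrip_matrix_io(matrix, path=None):
    """Write a matrix to text and read it back (helper for IO validation)."""
    import tempfile

    m = np.asarray(matrix, dtype=float)
    if path is None:
        with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as f:
            path = f.name
    asio.write_matrix(path, m)
    back, _ = asio.read_matrix(path)
    return back
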