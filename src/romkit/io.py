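"""Readers, writers and run configuration.

All interchange formats are plain text: pose tables and ligament
definitions as CSV, frames and run configuration as JSON, meshes as
OBJ/PLY/STL via trimesh.  SDF grids are cached as NPZ keyed by a content
hash of the mesh and the grid parameters, so repeated runs skip the
expensive mesh-to-field sampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contact import JointModel
from .errors import InvalidInputError
from .geometry import SDFGrid, build_sdf, load_mesh
from .ligaments import Ligament

__all__ = ["RunConfig", "load_joint", "read_pose_table", "write_pose_table",
           "read_ligaments_csv", "write_ligaments_csv"]

POSE_COLUMNS = ["fe", "abad", "lar", "tx", "ty", "tz"]


def read_pose_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"pose table {path} missing columns "
                                f"{missing}")
    return df


def write_pose_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_ligaments_csv(path) -> list[Ligament]:
    df = pd.read_csv(path)
    ligs = []
    for _, row in df.iterrows():
        ligs.append(Ligament(
            name=str(row["name"]),
            origin=[row["origin_x"], row["origin_y"], row["origin_z"]],
            insertion=[row["insertion_x"], row["insertion_y"],
                       row["insertion_z"]],
            rest_length=float(row["rest_length_mm"]),
            n_segments=int(row.get("n_segments", 20))))
    return ligs


def write_ligaments_csv(ligaments, path) -> None:
    rows = [{
        "name": l.name,
        "origin_x": l.origin[0], "origin_y": l.origin[1],
        "origin_z": l.origin[2],
        "insertion_x": l.insertion[0], "insertion_y": l.insertion[1],
        "insertion_z": l.insertion[2],
        "rest_length_mm": l.rest_length, "n_segments": l.n_segments,
    } for l in ligaments]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a full simulation run (JSON-serializable).

    Paths are resolved relative to the config file's directory when loaded
    with :meth:`from_json`.
    """

    proximal_mesh: str = ""
    distal_mesh: str = ""
    ligaments: str = ""
    articular_vertices: list = field(default_factory=list)
    proximal_frame: list = field(default_factory=lambda: np.eye(4).tolist())
    distal_frame: list = field(default_factory=lambda: np.eye(4).tolist())
    flip_proximal_normals: bool = False
    flip_distal_normals: bool = False
    # pose lattice
    fe_range: tuple = (-180.0, 180.0)
    abad_range: tuple = (-90.0, 90.0)
    lar_range: tuple = (-180.0, 180.0)
    step: float = 5.0
    # SDF
    sdf_resolution: int = 101
    sdf_half_extent: float | None = None   # default: 1.5 x articular radius
    sdf_center: list | None = None         # default: articular centroid
    build_distal_sdf: bool = True
    # contact optimization
    d_t: float | None = None
    lam: float = 1.0
    tol_penetration: float = 1e-3
    tol_congruence_frac: float = 0.1
    max_iter: int = 200
    translation_bound: float | None = None
    n_retries: int = 3
    warm_start: bool = True
    # thresholds & volumes
    threshold_mode: str = "scaled_rest_plus_strain"
    strain_factor: float = 0.26
    threshold_scale: float = 1.0
    trajectory: str = ""
    alpha: float | str = "auto"
    mc_samples: int = 100_000
    seed: int = 0
    out_dir: str = "romkit_out"
    cache_dir: str = ""

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        for attr in ("proximal_mesh", "distal_mesh", "ligaments",
                     "trajectory", "out_dir", "cache_dir"):
            value = getattr(cfg, attr)
            if value:
                setattr(cfg, attr, str((path.parent / value).resolve()))
        return cfg

    def to_json(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=list)

    def contact_config(self):
        from .contact import ContactConfig

        return ContactConfig(
            d_t=self.d_t, lam=self.lam,
            tol_penetration=self.tol_penetration,
            tol_congruence_frac=self.tol_congruence_frac,
            max_iter=self.max_iter,
            translation_bound=self.translation_bound,
            n_retries=self.n_retries, warm_start=self.warm_start)

    def pose_ranges(self) -> dict:
        return {"fe": tuple(self.fe_range), "abad": tuple(self.abad_range),
                "lar": tuple(self.lar_range)}


def _mesh_hash(mesh) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(mesh.vertices, dtype=np.float64).tobytes())
    h.update(np.asarray(mesh.faces, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


def _cached_sdf(mesh, center, half_extent, resolution,
                cache_dir: str) -> SDFGrid:
    if not cache_dir:
        return build_sdf(mesh, center, half_extent, resolution)
    key = hashlib.sha256(
        (_mesh_hash(mesh)
         + repr((np.round(np.asarray(center, float), 9).tolist(),
                 round(float(half_extent), 9), int(resolution)))
         ).encode()).hexdigest()[:24]
    path = Path(cache_dir) / f"sdf_{key}.npz"
    if path.exists():
        return SDFGrid.load(path)
    grid = build_sdf(mesh, center, half_extent, resolution)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid.save(path)
    return grid


def load_joint(config: RunConfig) -> JointModel:
    """Assemble a :class:`JointModel` from a run configuration.

    Builds (or loads from cache) the proximal — and optionally distal —
    SDF grids, centred by default on the articular surface centroid with a
    half-extent of 1.5x its bounding radius.
    """
    for p in (config.proximal_mesh, config.distal_mesh):
        if not Path(p).exists():
            raise InvalidInputError(f"mesh file not found: {p}")
    prox = load_mesh(config.proximal_mesh, config.flip_proximal_normals)
    dist = load_mesh(config.distal_mesh, config.flip_distal_normals)
    art = np.asarray(config.articular_vertices, dtype=int)
    if art.size == 0:
        raise InvalidInputError("articular_vertices must be provided")
    if art.min() < 0 or art.max() >= len(dist.vertices):
        raise InvalidInputError("articular vertex index out of range")
    pts = np.asarray(dist.vertices)[art]
    center = (np.asarray(config.sdf_center, float)
              if config.sdf_center is not None else pts.mean(axis=0))
    radius = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())
    half_extent = (config.sdf_half_extent
                   if config.sdf_half_extent is not None
                   else max(1.5 * radius, 1e-6))
    sdf = _cached_sdf(prox, center, half_extent, config.sdf_resolution,
                      config.cache_dir)
    distal_sdf = None
    if config.build_distal_sdf:
        distal_sdf = _cached_sdf(dist, center, half_extent,
                                 config.sdf_resolution, config.cache_dir)
    ligaments = (read_ligaments_csv(config.ligaments)
                 if config.ligaments else [])
    return JointModel(
        proximal_mesh=prox, proximal_sdf=sdf, distal_mesh=dist,
        articular_vertices=art,
        proximal_frame=np.asarray(config.proximal_frame, float),
        distal_frame=np.asarray(config.distal_frame, float),
        d_t=config.d_t, distal_sdf=distal_sdf, ligaments=ligaments)
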