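"""Strain-constrained mobility envelopes and alpha-shape volumetry.

The osteological mobility envelope (the viable pose set from the contact
simulation) is cut down by ligament length thresholds: any pose in which a
ligament would have to exceed its maximum sustainable length is discarded.
Envelopes are quantified as alpha-shape volumes of the pose cloud in the
sine-corrected rotation space (deg^3): the alpha complex keeps the
Delaunay tetrahedra whose circumradius is at most alpha, a parameterized
tightening of the convex hull.  Differences between envelopes ("missed"
volume) are estimated by Monte-Carlo integration of one shape against the
other, since exact Boolean operations on 3-D alpha shapes are brittle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .errors import InvalidInputError

__all__ = ["StrainThresholds", "AlphaComplex", "MobilityVolume",
           "derive_thresholds", "apply_strain_filter", "alpha_volume",
           "missed_volume", "alpha_sensitivity", "smallest_connecting_alpha"]


@dataclass
class StrainThresholds:
    """Per-ligament maximum admissible lengths (mm) with provenance.

    ``mode`` records how the thresholds were derived: directly from the
    maxima of an experimental trajectory (``trajectory_max``), from scaled
    dissection rest lengths plus a failure-strain factor
    (``scaled_rest_plus_strain``), or from ROM-interpolated lengths at the
    trajectory's rotational coordinates (``rom_interpolated``).
    """

    max_length: dict
    mode: str = "trajectory_max"

    def __post_init__(self):
        for name, v in self.max_length.items():
            if v <= 0:
                raise InvalidInputError(
                    f"threshold for {name} must be positive")


def derive_thresholds(mode: str, *, trajectory: pd.DataFrame | None = None,
                      ligaments=None, scale: float = 1.0,
                      strain_factor: float = 0.26,
                      rom_table: pd.DataFrame | None = None,
                      corrected_coords=None) -> StrainThresholds:
    """Derive per-ligament maximum-length thresholds.

    Modes
    -----
    ``trajectory_max``
        Maximum of each ``len_<name>`` column of ``trajectory``.
    ``scaled_rest_plus_strain``
        ``rest_length * scale * (1 + strain_factor)`` per ligament; the
        default factor of 0.26 is the mean failure strain reported for the
        acrocoracohumeral ligament in pigeon tensile experiments.
    ``rom_interpolated``
        ROM-dataset lengths interpolated (linearly, over sine-corrected
        rotational coordinates) at the trajectory's rotational poses —
        retaining the ROM set's optimized translations — then maximized.
    """
    if mode == "trajectory_max":
        if trajectory is None or len(trajectory) == 0:
            raise InvalidInputError("trajectory_max requires a non-empty "
                                    "trajectory table")
        cols = [c for c in trajectory.columns if c.startswith("len_")]
        if not cols:
            raise InvalidInputError("trajectory has no len_<name> columns")
        return StrainThresholds(
            {c[4:]: float(trajectory[c].max()) for c in cols}, mode)
    if mode == "scaled_rest_plus_strain":
        if not ligaments:
            raise InvalidInputError("scaled_rest_plus_strain requires "
                                    "ligaments with rest lengths")
        return StrainThresholds(
            {l.name: l.rest_length * scale * (1.0 + strain_factor)
             for l in ligaments}, mode)
    if mode == "rom_interpolated":
        from scipy.interpolate import (LinearNDInterpolator,
                                       NearestNDInterpolator)

        from .posespace import sine_correct

        if trajectory is None or len(trajectory) == 0 or rom_table is None:
            raise InvalidInputError("rom_interpolated requires trajectory "
                                    "and rom_table")
        rom_sc = sine_correct(rom_table[["fe", "abad", "lar"]].to_numpy())
        trj_sc = sine_correct(trajectory[["fe", "abad", "lar"]].to_numpy())
        out = {}
        for c in (c for c in rom_table.columns if c.startswith("len_")):
            vals = rom_table[c].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            interp = LinearNDInterpolator(rom_sc[ok], vals[ok])
            est = interp(trj_sc)
            nan = ~np.isfinite(est)
            if np.any(nan):
                est[nan] = NearestNDInterpolator(rom_sc[ok], vals[ok])(
                    trj_sc[nan])
            out[c[4:]] = float(np.nanmax(est))
        return StrainThresholds(out, mode)
    raise InvalidInputError(f"unknown threshold mode {mode!r}")


def apply_strain_filter(viable_mask: np.ndarray, length_table: pd.DataFrame,
                        thresholds: StrainThresholds) -> np.ndarray:
    """Mask of poses that are both osteologically viable and ligament-safe.

    ``length_table`` must hold one row per lattice pose (after failed-solve
    interpolation) with a ``len_<name>`` column for every thresholded
    ligament.  A pose survives only if every ligament stays at or below
    its maximum length.
    """
    viable_mask = np.asarray(viable_mask, dtype=bool)
    if len(length_table) != len(viable_mask):
        raise InvalidInputError("length table and viability mask disagree "
                                "on the number of poses")
    ok = viable_mask.copy()
    for name, limit in thresholds.max_length.items():
        col = f"len_{name}"
        if col not in length_table.columns:
            raise InvalidInputError(f"length table is missing column {col}")
        ok &= length_table[col].to_numpy(dtype=float) <= limit
    return ok


# ----------------------------------------------------------------------
def _tet_volumes(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (pts[tets[:, k]] for k in range(4))
    return np.abs(np.einsum("ij,ij->i", b - a,
                            np.cross(c - a, d - a))) / 6.0


def _tet_circumradii(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius per tetrahedron (inf for degenerate ones)."""
    a = pts[tets[:, 0]]
    M = np.stack([pts[tets[:, k]] - a for k in (1, 2, 3)], axis=1)  # (n,3,3)
    rhs = 0.5 * np.einsum("nij,nij->ni", M, M)
    det = np.linalg.det(M)
    ok = np.abs(det) > 1e-12
    centers = np.full((len(tets), 3), np.nan)
    if np.any(ok):
        centers[ok] = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
    r = np.full(len(tets), np.inf)
    r[ok] = np.linalg.norm(centers[ok], axis=1)
    # flat (zero-volume) tets from degenerate point sets — e.g. exact
    # lattices — still have a finite circumradius when their corners are
    # cocircular; least squares recovers it so these slivers can glue the
    # complex together without adding volume
    for i in np.flatnonzero(~ok):
        c, *_ = np.linalg.lstsq(M[i], rhs[i], rcond=None)
        if np.allclose(M[i] @ c, rhs[i], atol=1e-9):
            r[i] = np.linalg.norm(c)
    return r


@dataclass
class AlphaComplex:
    """Alpha complex of a 3-D point cloud: kept Delaunay tetrahedra."""

    points: np.ndarray
    alpha: float
    delaunay: Delaunay | None = field(repr=False, default=None)
    kept: np.ndarray = field(repr=False, default=None)  # bool per simplex

    @classmethod
    def build(cls, points, alpha: float) -> "AlphaComplex":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError("points must be (n, 3)")
        if len(pts) < 4:
            return cls(points=pts, alpha=alpha)
        try:
            tri = Delaunay(pts)
        except Exception:
            return cls(points=pts, alpha=alpha)  # degenerate (coplanar) set
        radii = _tet_circumradii(pts, tri.simplices)
        return cls(points=pts, alpha=alpha, delaunay=tri,
                   kept=radii <= alpha)

    @property
    def volume(self) -> float:
        if self.delaunay is None or not np.any(self.kept):
            return 0.0
        return float(_tet_volumes(self.points,
                                  self.delaunay.simplices[self.kept]).sum())

    def n_components(self) -> int:
        """Connected components of the kept tetrahedra (face adjacency)."""
        if self.delaunay is None or not np.any(self.kept):
            return 0
        kept_idx = np.flatnonzero(self.kept)
        pos = -np.ones(len(self.kept), dtype=int)
        pos[kept_idx] = np.arange(len(kept_idx))
        nbr = self.delaunay.neighbors[kept_idx]
        rows, cols = [], []
        for k in range(4):
            nb = nbr[:, k]
            ok = (nb >= 0) & self.kept[np.maximum(nb, 0)]
            rows.append(np.arange(len(kept_idx))[ok])
            cols.append(pos[nb[ok]])
        g = coo_matrix((np.ones(sum(len(r) for r in rows)),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(len(kept_idx), len(kept_idx)))
        return int(connected_components(g, directed=False)[0])

    def contains(self, query: np.ndarray) -> np.ndarray:
        """Whether each query point lies inside a kept tetrahedron."""
        if self.delaunay is None:
            return np.zeros(len(np.atleast_2d(query)), dtype=bool)
        simplex = self.delaunay.find_simplex(np.atleast_2d(query))
        inside = simplex >= 0
        inside[inside] = self.kept[simplex[inside]]
        return inside

    def sample(self, n: int, rng) -> np.ndarray:
        """Uniform random points inside the shape (volume-weighted by tet)."""
        tets = self.delaunay.simplices[self.kept]
        vols = _tet_volumes(self.points, tets)
        probs = vols / vols.sum()
        choice = rng.choice(len(tets), size=n, p=probs)
        bary = rng.dirichlet(np.ones(4), size=n)
        corners = self.points[tets[choice]]  # (n, 4, 3)
        return np.einsum("nk,nkj->nj", bary, corners)


@dataclass
class MobilityVolume:
    """An envelope's point cloud, alpha value and alpha-shape volume."""

    points: np.ndarray
    alpha: float
    volume: float  # deg^3
    n_components: int = 0


def alpha_volume(points, alpha: float) -> MobilityVolume:
    """Alpha-shape volume (deg^3) of a corrected-space pose cloud.

    Degenerate clouds (fewer than 4 affinely independent points) yield
    volume 0.
    """
    shape = AlphaComplex.build(points, alpha)
    return MobilityVolume(points=shape.points, alpha=alpha,
                          volume=shape.volume,
                          n_components=shape.n_components())


def missed_volume(reference, candidate, alpha: float,
                  n_samples: int = 100_000, seed: int = 0,
                  alpha_candidate: float | None = None):
    """Volume of the reference envelope not covered by the candidate.

    Monte-Carlo estimate: uniform samples inside the reference alpha shape
    are tested against the candidate's shape.  Returns
    ``(missed_deg3, missed_pct, mc_standard_error_deg3)``.
    """
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        raise InvalidInputError("reference pose set is empty")
    ref = AlphaComplex.build(reference, alpha)
    if ref.delaunay is None or ref.volume == 0.0:
        raise InvalidInputError("reference envelope is degenerate "
                                "(zero alpha-shape volume)")
    cand = AlphaComplex.build(candidate,
                              alpha if alpha_candidate is None
                              else alpha_candidate)
    rng = np.random.default_rng(seed)
    samples = ref.sample(int(n_samples), rng)
    outside = ~cand.contains(samples)
    frac = outside.mean()
    v_ref = ref.volume
    se = v_ref * np.sqrt(max(frac * (1 - frac), 0.0) / len(samples))
    return frac * v_ref, 100.0 * frac, se


def alpha_sensitivity(points, alphas) -> pd.DataFrame:
    """Volume-vs-alpha curve with connectivity diagnostics.

    Returns a DataFrame with ``alpha``, ``volume`` and ``n_components``
    rows (volumes are non-decreasing in alpha); the smallest alpha with a
    single connected component is the suggested per-dataset default.
    """
    alphas = np.sort(np.asarray(alphas, dtype=float))
    if len(alphas) < 2:
        raise InvalidInputError("need at least two alpha values")
    rows = [(a, (mv := alpha_volume(points, a)).volume, mv.n_components)
            for a in alphas]
    return pd.DataFrame(rows, columns=["alpha", "volume", "n_components"])


def smallest_connecting_alpha(points, alphas) -> float | None:
    """Smallest alpha from the list giving one connected component."""
    curve = alpha_sensitivity(points, alphas)
    hit = curve[(curve.n_components == 1) & (curve.volume > 0)]
    return None if hit.empty else float(hit.alpha.iloc[0])
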