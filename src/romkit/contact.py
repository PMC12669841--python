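"""Contact-optimized six-DOF range-of-motion simulation.

For every rotational pose on a lattice, the translational joint position is
optimized so that the distal bone's articular surface stays congruent with
the proximal bone: the mean signed distance ("joint proximity") of the
articular vertices, evaluated in the proximal bone's SDF, is driven towards
a target spacing ``d_t`` while the proximity variance is minimized for
maximal congruence, subject to per-vertex non-penetration::

    C_ROM(t) = (mean_v d_v(t) - d_t)^2 + lambda * Var_v d_v(t)
    s.t.      d_v(t) >= 0   for every articular vertex v

solved with SLSQP.  A pose is osteologically viable when the solver
converges to a feasible, congruent placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize

from .errors import InvalidInputError, OutOfDomainError
from .geometry import SDFGrid
from .posespace import Pose, PoseGrid, rotation_matrix

__all__ = ["ContactConfig", "JointModel", "PoseSolution", "MobilityResult",
           "proximity_stats", "optimize_translation", "simulate_rom"]

log = logging.getLogger(__name__)

# fixed retry offsets (mm) applied to the initial translation when a solve
# fails; deterministic by construction
_RETRY_OFFSETS = np.array([[0.3, 0.0, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.3]])


@dataclass
class ContactConfig:
    """Tunables of the translational contact optimization.

    ``d_t`` (mm) is the target joint proximity — in real use a
    cartilage-informed spacing; ``None`` defaults to half the proximal SDF
    grid spacing.  ``lam`` weights the congruence (variance) term.
    ``translation_bound`` (mm) is a symmetric box bound on the optimized
    translation; ``None`` defaults to twice the articular surface's
    bounding radius.  Setting it to 0 reduces the simulation to a classic
    fixed-centre ROM map.
    """

    d_t: float | None = None
    lam: float = 1.0
    tol_penetration: float = 1e-3
    tol_congruence_frac: float = 0.1
    max_iter: int = 200
    translation_bound: float | None = None
    warm_start: bool = True
    n_retries: int = 3


@dataclass
class JointModel:
    """Two bones, their SDFs, frames, articular subset and ligaments."""

    proximal_mesh: trimesh.Trimesh
    proximal_sdf: SDFGrid
    distal_mesh: trimesh.Trimesh
    articular_vertices: np.ndarray
    proximal_frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    distal_frame: np.ndarray = field(default_factory=lambda: np.eye(4))
    d_t: float | None = None
    distal_sdf: SDFGrid | None = None
    ligaments: list = field(default_factory=list)

    def __post_init__(self):
        self.articular_vertices = np.asarray(self.articular_vertices,
                                             dtype=int)
        if self.articular_vertices.size == 0:
            raise InvalidInputError("articular_vertices must be non-empty")
        n = len(self.distal_mesh.vertices)
        if (self.articular_vertices.min() < 0
                or self.articular_vertices.max() >= n):
            raise InvalidInputError("articular vertex index out of range")
        if self.d_t is not None and self.d_t < 0:
            raise InvalidInputError("d_t must be non-negative")

    @property
    def articular_points(self) -> np.ndarray:
        """Articular vertex positions in distal-bone coordinates."""
        return np.asarray(self.distal_mesh.vertices)[self.articular_vertices]

    def articular_radius(self) -> float:
        pts = self.articular_points
        return float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())

    def target_proximity(self, config: "ContactConfig | None" = None) -> float:
        if config is not None and config.d_t is not None:
            return config.d_t
        if self.d_t is not None:
            return self.d_t
        return 0.5 * self.proximal_sdf.spacing


@dataclass
class PoseSolution:
    """Outcome of the translational optimization at one rotational pose."""

    pose: Pose
    mean_proximity: float
    proximity_variance: float
    min_proximity: float
    converged: bool
    objective: float
    n_iter: int


class _PoseGeometry:
    """Pose-fixed linear map from translation to world-space vertices.

    With the pose rotation R fixed, the articular vertices move as
    ``w_v(t) = base_v + A t`` where ``A`` is the (constant) rotation part
    of the proximal joint frame — translations are expressed in that frame.
    """

    def __init__(self, joint: JointModel, angles):
        R = rotation_matrix(*angles)
        P, D = joint.proximal_frame, joint.distal_frame
        Dinv = np.linalg.inv(D)
        x = joint.articular_points
        local = (Dinv[:3, :3] @ x.T).T + Dinv[:3, 3]
        self.base = (P[:3, :3] @ (R @ local.T)).T + P[:3, 3]
        self.A = P[:3, :3]
        self.sdf = joint.proximal_sdf
        self._cache_key = None
        self._cache_val = None

    def distances(self, t: np.ndarray):
        """Per-vertex signed distances and their gradients w.r.t. t."""
        key = t.tobytes()
        if key != self._cache_key:
            pts = self.base + self.A @ t
            d, g = self.sdf.sample_with_gradient(pts)
            self._cache_val = (d, g @ self.A)
            self._cache_key = key
        return self._cache_val


def proximity_stats(joint: JointModel, transform: np.ndarray):
    """Per-vertex proximities under an explicit rigid transform.

    Returns ``(distances, mean, variance, minimum)`` where distances are
    the proximal-SDF values at the transformed distal articular vertices.
    Variance is the population variance over exactly ``n_v`` values.
    """
    T = np.asarray(transform, dtype=float)
    pts = (T[:3, :3] @ joint.articular_points.T).T + T[:3, 3]
    d = np.atleast_1d(joint.proximal_sdf.sample(pts))
    return d, float(d.mean()), float(d.var()), float(d.min())


def _solve_single(geom: _PoseGeometry, d_t: float, config: ContactConfig,
                  init: np.ndarray, bound: float):
    """One SLSQP solve; returns (t, stats, success, n_iter) or None on domain exit."""

    def fun(t):
        d, _ = geom.distances(t)
        return (d.mean() - d_t) ** 2 + config.lam * d.var()

    def jac(t):
        d, g = geom.distances(t)
        mean = d.mean()
        gmean = g.mean(axis=0)
        gvar = 2.0 * ((d - mean)[:, None] * g).mean(axis=0)
        return 2.0 * (mean - d_t) * gmean + config.lam * gvar

    cons = {
        "type": "ineq",
        "fun": lambda t: geom.distances(t)[0],
        "jac": lambda t: geom.distances(t)[1],
    }
    bounds = [(-bound, bound)] * 3
    try:
        res = minimize(fun, init, jac=jac, method="SLSQP", bounds=bounds,
                       constraints=[cons],
                       options={"maxiter": config.max_iter, "ftol": 1e-10})
    except OutOfDomainError:
        return None
    return res


def optimize_translation(joint: JointModel, rotation, init=None,
                         config: ContactConfig | None = None) -> PoseSolution:
    """Optimize the translational joint position for one rotational pose.

    ``rotation`` is ``(fe, abad, lar)`` in degrees (or a :class:`Pose`,
    whose translation is ignored).  Non-convergence and infeasibility are
    reported via ``converged=False``, never raised.  Deterministic given
    (joint, rotation, init, config).
    """
    config = config or ContactConfig()
    angles = rotation.angles if isinstance(rotation, Pose) else \
        np.asarray(rotation, dtype=float)
    d_t = joint.target_proximity(config)
    bound = config.translation_bound
    if bound is None:
        bound = 2.0 * joint.articular_radius()
    geom = _PoseGeometry(joint, angles)
    init = np.zeros(3) if init is None else np.asarray(init, dtype=float)
    tol_cong = config.tol_congruence_frac * max(d_t, 1e-6)

    def classify(t):
        try:
            d, _ = geom.distances(t)
        except OutOfDomainError:
            return None
        mean, var, mn = float(d.mean()), float(d.var()), float(d.min())
        obj = (mean - d_t) ** 2 + config.lam * var
        feasible = (mn >= -config.tol_penetration
                    and abs(mean - d_t) <= tol_cong)
        return mean, var, mn, obj, feasible

    if bound == 0.0:
        out = classify(np.zeros(3))
        if out is None:
            return PoseSolution(Pose(*angles), np.nan, np.nan, np.nan,
                                False, np.nan, 0)
        mean, var, mn, obj, feasible = out
        return PoseSolution(Pose(*angles), mean, var, mn, feasible, obj, 0)

    inits = [init]
    inits += [init + off for off in _RETRY_OFFSETS[:max(0, config.n_retries)]]
    best = None
    for trial, x0 in enumerate(inits):
        x0 = np.clip(x0, -bound, bound)
        res = _solve_single(geom, d_t, config, x0, bound)
        if res is None:  # SDF domain exit during the solve: damp the start
            res = _solve_single(geom, d_t, config, 0.5 * x0, bound)
        if res is None:
            continue
        out = classify(res.x)
        if out is None:
            continue
        mean, var, mn, obj, feasible = out
        sol = PoseSolution(
            Pose(*angles, *res.x), mean, var, mn,
            bool(res.success and feasible), obj, int(res.nit))
        if sol.converged:
            return sol
        if best is None or sol.objective < best.objective:
            best = sol
    if best is None:
        best = PoseSolution(Pose(*angles), np.nan, np.nan, np.nan, False,
                            np.nan, 0)
    return best


@dataclass
class MobilityResult:
    """Per-pose solutions of a lattice ROM simulation."""

    grid: PoseGrid
    translations: np.ndarray  # (n, 3) mm
    mean_proximity: np.ndarray
    proximity_variance: np.ndarray
    min_proximity: np.ndarray
    converged: np.ndarray  # bool
    objective: np.ndarray
    n_iter: np.ndarray

    @property
    def viable_mask(self) -> np.ndarray:
        return self.converged

    @property
    def solutions(self) -> list:
        return [
            PoseSolution(
                Pose(*a, *t), m, v, mn, bool(c), o, int(ni))
            for a, t, m, v, mn, c, o, ni in zip(
                self.grid.angles, self.translations, self.mean_proximity,
                self.proximity_variance, self.min_proximity, self.converged,
                self.objective, self.n_iter)
        ]

    def to_dataframe(self):
        import pandas as pd

        a, t = self.grid.angles, self.translations
        return pd.DataFrame({
            "fe": a[:, 0], "abad": a[:, 1], "lar": a[:, 2],
            "tx": t[:, 0], "ty": t[:, 1], "tz": t[:, 2],
            "mean_prox": self.mean_proximity,
            "var_prox": self.proximity_variance,
            "min_prox": self.min_proximity,
            "converged": self.converged,
            "viable": self.viable_mask,
        })


def simulate_rom(joint: JointModel, grid: PoseGrid,
                 config: ContactConfig | None = None) -> MobilityResult:
    """Run the translational contact optimization over a full pose lattice.

    Each pose is warm-started from the nearest already-solved lattice
    neighbour (falling back to zero translation), which accelerates the
    sweep without changing well-converged solutions; poses exactly on
    the viability margin can classify differently than with cold starts
    (``warm_start=False``).
    """
    config = config or ContactConfig()
    n = len(grid)
    shape = grid.shape
    trans = np.full((n, 3), np.nan)
    mean = np.full(n, np.nan)
    var = np.full(n, np.nan)
    mn = np.full(n, np.nan)
    conv = np.zeros(n, dtype=bool)
    obj = np.full(n, np.nan)
    nit = np.zeros(n, dtype=int)

    strides = (shape[1] * shape[2], shape[2], 1)
    idx3 = np.stack(np.unravel_index(np.arange(n), shape), axis=-1)

    for i in range(n):
        init = None
        if config.warm_start:
            # predecessor neighbours along each lattice axis
            for ax in (2, 1, 0):
                if idx3[i, ax] > 0:
                    j = i - strides[ax]
                    if conv[j]:
                        init = trans[j]
                        break
        sol = optimize_translation(joint, grid.angles[i], init=init,
                                   config=config)
        trans[i] = sol.pose.translation
        mean[i], var[i], mn[i] = (sol.mean_proximity,
                                  sol.proximity_variance, sol.min_proximity)
        conv[i] = sol.converged
        obj[i] = sol.objective
        nit[i] = sol.n_iter
        if (i + 1) % 500 == 0:
            log.info("ROM sweep: %d/%d poses, %.1f%% viable so far",
                     i + 1, n, 100.0 * conv[:i + 1].mean())

    return MobilityResult(grid=grid, translations=trans, mean_proximity=mean,
                          proximity_variance=var, min_proximity=mn,
                          converged=conv, objective=obj, n_iter=nit)
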