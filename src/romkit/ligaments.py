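"""Motion-independent ligament paths as shortest obstacle-avoiding polylines.

A ligament is modelled as a polyline of ``n + 1`` points from origin
``p_0`` to insertion ``p_n``, expressed in a ligament frame whose X-axis
runs along ``p_0 -> p_n``.  The points are fixed at equidistant stations
along X; only their ``(y, z)`` coordinates are free.  The path solver
minimizes the total Euclidean length subject to (i) a non-negative signed
distance from every interior point to every bony obstacle (bones given as
SDF grids with rigid placements) and (ii) a per-segment angular offset to
the ligament long axis of at most 60 degrees, which keeps the optimized
path smooth and prevents it from cutting through a bone between stations.

Because each pose is solved independently from the same straight-line
start, ligament lengths are strictly motion independent: the same pose
always yields the same length regardless of the order in which poses are
evaluated — the property that history-dependent cloth simulations violate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import DegenerateFrameError, InvalidInputError, OutOfDomainError
from .geometry import SDFGrid
from .posespace import Pose, pose_to_transform, sine_correct

__all__ = ["Ligament", "LigamentFrame", "LigamentPath", "PathConfig",
           "Obstacle", "ligament_frame", "solve_ligament_path",
           "path_length_for_pose", "compute_strain", "evaluate_ligaments",
           "interpolate_failed_lengths"]

#: Maximum angle (deg) between any path segment and the ligament long axis.
MAX_SEGMENT_ANGLE_DEG = 60.0


@dataclass(frozen=True)
class Ligament:
    """Named ligament with bone-local attachment points and rest length."""

    name: str
    origin: np.ndarray     # proximal-bone coordinates (mm)
    insertion: np.ndarray  # distal-bone coordinates (mm)
    rest_length: float     # mm
    n_segments: int = 20

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "insertion",
                           np.asarray(self.insertion, float))
        if self.rest_length <= 0:
            raise InvalidInputError("rest_length must be positive")
        if self.n_segments < 2:
            raise InvalidInputError("n_segments must be >= 2")


@dataclass(frozen=True)
class LigamentFrame:
    """Right-handed orthonormal frame attached to a ligament's chord."""

    p0: np.ndarray
    pn: np.ndarray
    axes: np.ndarray  # rows are the X, Y, Z unit vectors (world coords)

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.pn - self.p0))

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return np.atleast_2d(local) @ self.axes + self.p0

    def to_local(self, world: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(world) - self.p0) @ self.axes.T


@dataclass
class Obstacle:
    """An SDF grid with a rigid placement in the world frame.

    ``transform`` maps world coordinates into the grid's own frame (i.e.
    the inverse of the bone's pose).  Identity for a static bone whose SDF
    was built in world coordinates.
    """

    sdf: SDFGrid
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def distance_and_gradient(self, world_pts: np.ndarray):
        T = self.transform
        local = (T[:3, :3] @ np.atleast_2d(world_pts).T).T + T[:3, 3]
        d, g = self.sdf.sample_with_gradient(local)
        return d, g @ T[:3, :3]


@dataclass
class LigamentPath:
    """Solved path polyline with total length.

    ``local`` holds the points in ligament-frame coordinates (the x column
    is exactly the fixed equidistant stations); ``world`` the same points
    in world coordinates.
    """

    local: np.ndarray
    world: np.ndarray
    length: float
    converged: bool


@dataclass
class PathConfig:
    max_iter: int = 150
    tol_distance: float = 1e-6
    lift_margin_frac: float = 0.5   # lift clearance as a fraction of grid spacing
    straight_tol: float = 1e-9


def ligament_frame(p0, pn, pj) -> LigamentFrame:
    """Ligament frame from origin, insertion and joint centre.

    X runs from origin to insertion; Y is the (normalized) cross product
    of X with the origin-to-joint-centre vector; Z completes the
    right-handed triad.  A joint centre collinear with the chord leaves Y
    undefined and raises :class:`DegenerateFrameError`.
    """
    p0 = np.asarray(p0, float)
    pn = np.asarray(pn, float)
    pj = np.asarray(pj, float)
    chord = pn - p0
    L = np.linalg.norm(chord)
    if L == 0:
        raise InvalidInputError("ligament origin and insertion coincide")
    X = chord / L
    cross = np.cross(X, pj - p0)
    norm = np.linalg.norm(cross)
    if norm < 1e-9 * max(1.0, np.linalg.norm(pj - p0)):
        raise DegenerateFrameError(
            "joint centre is collinear with the ligament chord; supply an "
            "alternative up-hint")
    Y = cross / norm
    Z = np.cross(X, Y)
    return LigamentFrame(p0=p0, pn=pn, axes=np.stack([X, Y, Z]))


def _stations(frame: LigamentFrame, n: int) -> np.ndarray:
    return frame.chord_length * np.arange(n + 1) / n


def _path_points(frame: LigamentFrame, yz: np.ndarray, n: int) -> np.ndarray:
    """Full local polyline from the free interior (y, z) coordinates."""
    pts = np.zeros((n + 1, 3))
    pts[:, 0] = _stations(frame, n)
    pts[1:n, 1:] = yz.reshape(n - 1, 2)
    return pts


def _lift_start(frame: LigamentFrame, obstacles, n: int,
                config: PathConfig) -> np.ndarray:
    """Push penetrating interior points of the straight start out of the bones.

    Points are moved within their fixed-x plane along the obstacle SDF
    gradient (projected onto the frame's YZ plane); if the gradient has no
    usable YZ component — e.g. exactly on a symmetry axis — the frame's +Z
    is used, which by construction points away from the joint centre.
    This only prepares a feasible-ish start; optimality is SLSQP's job.
    """
    yz = np.zeros((n - 1, 2))
    YZ = frame.axes[1:]  # (2, 3) world directions of local y, z
    for _ in range(30):
        pts_world = frame.to_world(_path_points(frame, yz, n))[1:n]
        worst = np.full(n - 1, np.inf)
        push = np.zeros((n - 1, 2))
        for obs in obstacles:
            try:
                d, g = obs.distance_and_gradient(pts_world)
            except OutOfDomainError:
                return yz
            sel = d < worst
            worst[sel] = d[sel]
            push[sel] = (g @ YZ.T)[sel]
        margin = config.lift_margin_frac * min(o.sdf.spacing
                                               for o in obstacles)
        bad = worst < margin
        if not np.any(bad):
            break
        norms = np.linalg.norm(push[bad], axis=1)
        dirs = np.where(norms[:, None] > 1e-3,
                        push[bad] / np.maximum(norms, 1e-9)[:, None],
                        np.array([0.0, 1.0]))  # local +Z: away from joint centre
        yz[bad] += (margin - worst[bad])[:, None] * dirs
    return yz


def solve_ligament_path(frame: LigamentFrame, obstacles, n_segments: int = 20,
                        config: PathConfig | None = None) -> LigamentPath:
    """Shortest admissible path from origin to insertion around the obstacles.

    Free variables are the interior points' (y, z) coordinates in the
    ligament frame.  Starts from the straight chord (lifted out of any
    penetrated obstacle); if the straight chord is itself admissible it is
    returned directly, being the unconstrained optimum.
    """
    config = config or PathConfig()
    n = int(n_segments)
    if n < 2:
        raise InvalidInputError("n_segments must be >= 2")
    obstacles = [o if isinstance(o, Obstacle) else Obstacle(*o)
                 for o in obstacles]
    dx = frame.chord_length / n
    tan_max_sq = np.tan(np.radians(MAX_SEGMENT_ANGLE_DEG)) ** 2

    obs_cache: dict = {"key": None}

    def obstacle_eval(yz_flat):
        """Stacked obstacle distances and their YZ jacobian blocks, memoized."""
        key = yz_flat.tobytes()
        if obs_cache["key"] != key:
            pts = frame.to_world(_path_points(frame, yz_flat, n))[1:n]
            YZ = frame.axes[1:]
            dists, jacs = [], []
            for obs in obstacles:
                d, g = obs.distance_and_gradient(pts)
                dists.append(d)
                jacs.append(g @ YZ.T)
            obs_cache.update(key=key, d=np.concatenate(dists),
                             gyz=np.concatenate(jacs))
        return obs_cache

    def obstacle_min(yz_flat):
        if not obstacles:
            return np.array([np.inf])
        return obstacle_eval(yz_flat)["d"]

    # straight start (possibly lifted out of the bones)
    if obstacles:
        yz0 = _lift_start(frame, obstacles, n, config)
    else:
        yz0 = np.zeros((n - 1, 2))

    def finish(yz_flat, success):
        local = _path_points(frame, yz_flat, n)
        world = frame.to_world(local)
        seglen = np.linalg.norm(np.diff(world, axis=0), axis=1)
        length = float(seglen.sum())
        try:
            dist_ok = bool(np.all(obstacle_min(yz_flat) >=
                                  -config.tol_distance))
        except OutOfDomainError:
            dist_ok = False
        step = np.diff(local, axis=0)
        angle_ok = bool(np.all(step[:, 1] ** 2 + step[:, 2] ** 2
                               <= tan_max_sq * dx * dx + 1e-9))
        return LigamentPath(local=local, world=world, length=length,
                            converged=bool(success and dist_ok and angle_ok))

    if not obstacles:
        return finish(np.zeros(2 * (n - 1)), True)

    flat0 = yz0.ravel()
    if np.all(np.abs(flat0) < config.straight_tol):
        try:
            if np.all(obstacle_min(flat0) >= 0.0):
                return finish(flat0, True)
        except OutOfDomainError:
            pass

    # SLSQP over the interior (y, z) coordinates
    cache: dict = {"key": None}

    def geometry(yz_flat):
        key = yz_flat.tobytes()
        if cache["key"] != key:
            local = _path_points(frame, yz_flat, n)
            step = np.diff(local, axis=0)
            seglen = np.linalg.norm(step, axis=1)
            cache.update(key=key, local=local, step=step, seglen=seglen)
        return cache

    def fun(yz_flat):
        return geometry(yz_flat)["seglen"].sum()

    def jac(yz_flat):
        g = geometry(yz_flat)
        unit = g["step"] / g["seglen"][:, None]  # (n, 3)
        grad = np.zeros((n - 1, 2))
        grad += unit[:-1, 1:]   # point i ends segment i-1
        grad -= unit[1:, 1:]    # point i starts segment i
        return grad.ravel()

    def dist_fun(yz_flat):
        return obstacle_eval(yz_flat)["d"]

    def dist_jac(yz_flat):
        gyz = obstacle_eval(yz_flat)["gyz"]  # (n_obs * (n-1), 2)
        m = n - 1
        blocks = []
        for o in range(len(obstacles)):
            J = np.zeros((m, m * 2))
            J[np.arange(m), 2 * np.arange(m)] = gyz[o * m:(o + 1) * m, 0]
            J[np.arange(m), 2 * np.arange(m) + 1] = gyz[o * m:(o + 1) * m, 1]
            blocks.append(J)
        return np.vstack(blocks)

    def angle_fun(yz_flat):
        g = geometry(yz_flat)
        step = g["step"]
        return tan_max_sq * dx * dx - step[:, 1] ** 2 - step[:, 2] ** 2

    def angle_jac(yz_flat):
        g = geometry(yz_flat)
        step = g["step"]
        # segment s runs from point s to point s+1; free points are 1..n-1
        J = np.zeros((n, (n - 1) * 2))
        for s in range(n):
            dyz = step[s, 1:]
            if s + 1 <= n - 1:  # end point of segment s is free point s+1
                k = s  # free index of point s+1 is s
                J[s, 2 * k:2 * k + 2] += -2.0 * dyz
            if 1 <= s <= n - 1:  # start point of segment s is free point s
                k = s - 1
                J[s, 2 * k:2 * k + 2] += 2.0 * dyz
        return J

    constraints = [
        {"type": "ineq", "fun": dist_fun, "jac": dist_jac},
        {"type": "ineq", "fun": angle_fun, "jac": angle_jac},
    ]
    try:
        res = minimize(fun, flat0, jac=jac, method="SLSQP",
                       constraints=constraints,
                       options={"maxiter": config.max_iter, "ftol": 1e-12})
        return finish(res.x, res.success)
    except OutOfDomainError:
        return finish(flat0, False)


def compute_strain(length: float, rest_length: float) -> float:
    """Engineering strain in percent: ``100 * (length / rest - 1)``."""
    if rest_length <= 0:
        raise InvalidInputError("rest_length must be positive")
    return 100.0 * (np.asarray(length, float) / rest_length - 1.0)


def path_length_for_pose(joint, lig: Ligament, pose: Pose,
                         config: PathConfig | None = None,
                         up_hint=None, straight: bool = False):
    """Ligament path length (mm) at one joint pose.

    The insertion is carried by the pose transform into the proximal
    frame; the joint centre used for the ligament frame is the posed
    joint-frame origin (i.e. it follows the optimized translation).  Both
    bones act as obstacles when their SDFs are present.  Evaluation is
    stateless: identical poses give identical lengths in any order.

    With ``straight=True`` the plain origin-insertion distance is returned
    (the convention used for reporting intracapsular ligament strain).
    Returns ``(length, converged)``.
    """
    T = pose_to_transform(pose, joint.proximal_frame, joint.distal_frame)
    p0 = lig.origin
    pn = T[:3, :3] @ lig.insertion + T[:3, 3]
    if straight:
        return float(np.linalg.norm(pn - p0)), True
    pj = joint.proximal_frame[:3, :3] @ pose.translation + \
        joint.proximal_frame[:3, 3]
    try:
        frame = ligament_frame(p0, pn, pj)
    except DegenerateFrameError:
        hint = np.asarray(up_hint if up_hint is not None
                          else joint.proximal_frame[:3, 1])
        frame = ligament_frame(p0, pn, p0 + np.linalg.norm(pn - p0) * hint)
    obstacles = []
    if joint.proximal_sdf is not None:
        obstacles.append(Obstacle(joint.proximal_sdf, np.eye(4)))
    if joint.distal_sdf is not None:
        obstacles.append(Obstacle(joint.distal_sdf, np.linalg.inv(T)))
    path = solve_ligament_path(frame, obstacles, lig.n_segments, config)
    return path.length, path.converged


def evaluate_ligaments(joint, ligaments, poses, translations=None,
                       config: PathConfig | None = None) -> pd.DataFrame:
    """Batch ligament lengths/strains over a pose table.

    ``poses`` is an (n, 3) array of (fe, abad, lar) in degrees;
    ``translations`` an optional (n, 3) array of optimized joint
    translations (mm), zeros when omitted.  Returns a DataFrame with
    ``len_<name>``, ``strain_<name>`` and ``conv_<name>`` columns.
    """
    poses = np.atleast_2d(np.asarray(poses, float))
    if translations is None:
        translations = np.zeros((len(poses), 3))
    translations = np.asarray(translations, float)
    out = {"fe": poses[:, 0], "abad": poses[:, 1], "lar": poses[:, 2],
           "tx": translations[:, 0], "ty": translations[:, 1],
           "tz": translations[:, 2]}
    for lig in ligaments:
        lengths = np.empty(len(poses))
        conv = np.zeros(len(poses), dtype=bool)
        for i, (ang, t) in enumerate(zip(poses, translations)):
            pose = Pose(*ang, *t)
            lengths[i], conv[i] = path_length_for_pose(joint, lig, pose,
                                                       config)
        out[f"len_{lig.name}"] = lengths
        out[f"strain_{lig.name}"] = compute_strain(lengths, lig.rest_length)
        out[f"conv_{lig.name}"] = conv
    return pd.DataFrame(out)


def interpolate_failed_lengths(table: pd.DataFrame,
                               corrected_coords: np.ndarray | None = None,
                               n_neighbors: int = 26,
                               robust_z: float = 4.0,
                               skip_insufficient: bool = False
                               ) -> pd.DataFrame:
    """Replace failed (and robust-outlier) ligament lengths by interpolation.

    Entries whose ``conv_<name>`` flag is False are always replaced;
    additionally, converged entries deviating more than ``robust_z``
    median/MAD z-scores from their ``n_neighbors`` nearest neighbours in
    sine-corrected rotation space are flagged and replaced.  Replacement
    values come from linear barycentric interpolation over the Delaunay
    triangulation of the valid corrected coordinates, with a
    nearest-neighbour fallback outside the hull.
    """
    table = table.copy()
    if corrected_coords is None:
        corrected_coords = sine_correct(
            table[["fe", "abad", "lar"]].to_numpy())
    coords = np.asarray(corrected_coords, float)
    lig_names = [c[4:] for c in table.columns if c.startswith("len_")]
    for name in lig_names:
        lengths = table[f"len_{name}"].to_numpy(dtype=float)
        conv = table[f"conv_{name}"].to_numpy(dtype=bool)
        good = conv.copy()
        if good.sum() >= n_neighbors + 1:
            tree = cKDTree(coords[good])
            k = min(n_neighbors + 1, good.sum())
            _, nbr = tree.query(coords[good], k=k)
            vals = lengths[good][nbr[:, 1:]]
            med = np.median(vals, axis=1)
            mad = np.median(np.abs(vals - med[:, None]), axis=1)
            z = np.abs(lengths[good] - med) / np.maximum(1.4826 * mad, 1e-12)
            outlier = np.zeros_like(good)
            outlier[np.flatnonzero(good)] = z > robust_z
            good &= ~outlier
        if good.sum() < 4:
            if skip_insufficient:
                continue  # keep best-effort lengths for this ligament
            raise InvalidInputError(
                f"ligament {name}: fewer than 4 valid samples to "
                "interpolate from")
        bad = ~good
        if not np.any(bad):
            continue
        try:
            interp = LinearNDInterpolator(coords[good], lengths[good])
            filled = interp(coords[bad])
        except Exception:
            filled = np.full(bad.sum(), np.nan)
        nan = ~np.isfinite(filled)
        if np.any(nan):
            nn = NearestNDInterpolator(coords[good], lengths[good])
            filled[nan] = nn(coords[bad][nan])
        lengths[bad] = filled
        table[f"len_{name}"] = lengths
        table[f"interp_{name}"] = bad
    return table
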