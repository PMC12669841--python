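"""Synthetic joints, ligaments and trajectories with known ground truth.

These generators stand in for real bone scans: every other module can be
exercised — and checked against closed-form oracles — without any imaging
or experimental data.

* :func:`make_ball_and_socket` — an idealized spherical joint.  The socket
  is a sphere (or partial spherical shell) enclosing the ball with a
  uniform clearance, so the concentric placement is the analytically known
  contact optimum and every rotation is admissible.
* :func:`make_hemisellar` — a saddle-shaped articular surface with a
  congruent convex counter-surface, emulating an open saddle joint that
  permits translational sliding.  It is mirror-symmetric about the x = 0
  plane, which provides an exact symmetry oracle for the ROM optimizer.
* :func:`make_cylinder_obstacle` — an analytic cylinder field for which
  the wrapped ligament geodesic has a closed form (tangent lines + arc).
* :func:`make_ligament_set` — attachment points on the two bones with rest
  lengths defined as the solved path length at the reference pose.
* :func:`make_trajectory` — a smooth, band-limited pseudo-experimental
  pose trajectory with optional Gaussian noise.

All generation is deterministic given the parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import trimesh

from .contact import JointModel
from .errors import InvalidInputError
from .geometry import build_sdf, build_sdf_from_function
from .ligaments import Ligament, PathConfig, path_length_for_pose
from .posespace import Pose

__all__ = ["make_ball_and_socket", "make_hemisellar",
           "make_cylinder_obstacle", "make_ligament_set", "make_trajectory",
           "LIGAMENT_NAMES"]

#: Avian shoulder ligament names used for generated ligament sets
#: (acrocoracohumeral, coracohumeral, dorsal/lateral/posterior
#: scapulohumeral, intracapsular).
LIGAMENT_NAMES = ("LAcH", "LCoHd", "LScHd", "LScHl", "LScHp", "LIcCa")


def _socket_shell(r_inner: float, thickness: float, coverage_deg: float,
                  n_theta: int = 24, n_phi: int = 48) -> trimesh.Trimesh:
    """Watertight partial spherical shell opening towards +Z.

    Covers polar angles from the -Z pole up to ``coverage_deg`` (measured
    as the full cone angle of covered surface).
    """
    theta = np.radians(np.linspace(180.0 - coverage_deg / 2.0, 180.0,
                                   n_theta))  # from rim to -Z pole
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)

    def ring(r, th):
        return np.stack([r * np.sin(th) * np.cos(phi),
                         r * np.sin(th) * np.sin(phi),
                         np.full(n_phi, r * np.cos(th))], axis=-1)

    verts = []
    for r in (r_inner, r_inner + thickness):
        for th in theta[:-1]:
            verts.append(ring(r, th))
        verts.append(np.array([[0.0, 0.0, -r]]))  # pole vertex
    verts = np.concatenate(verts)

    n_rings = n_theta - 1
    inner_off, outer_off = 0, n_rings * n_phi + 1

    def vid(surface_off, ring_i, j):
        return surface_off + ring_i * n_phi + (j % n_phi)

    faces = []
    for off in (inner_off, outer_off):
        pole = off + n_rings * n_phi
        for i in range(n_rings - 1):
            for j in range(n_phi):
                a, b = vid(off, i, j), vid(off, i, j + 1)
                c, d = vid(off, i + 1, j), vid(off, i + 1, j + 1)
                faces += [[a, b, c], [b, d, c]]
        for j in range(n_phi):
            faces.append([vid(off, n_rings - 1, j),
                          vid(off, n_rings - 1, j + 1), pole])
    # rim annulus joining the two surfaces at theta[0]
    for j in range(n_phi):
        a, b = vid(inner_off, 0, j), vid(inner_off, 0, j + 1)
        c, d = vid(outer_off, 0, j), vid(outer_off, 0, j + 1)
        faces += [[a, c, b], [b, c, d]]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    return mesh


def make_ball_and_socket(r_ball: float = 5.0, clearance: float = 0.5,
                         coverage_deg: float = 360.0,
                         subdivisions: int = 3, sdf_resolution: int = 41,
                         with_distal_sdf: bool = False,
                         analytic_sdf: bool = True):
    """Ball-and-socket joint with uniform clearance.

    The socket surface is a sphere of radius ``r_ball + clearance``
    oriented with normals towards its centre (the bone material lies
    outside), so its signed distance field is exactly ``r_socket - |p|``.
    With ``coverage_deg < 360`` a partial shell cup opening towards +Z is
    generated instead.  Returns ``(joint, oracles)`` where ``oracles``
    holds closed-form SDF callables for both surfaces.

    By default the SDF grids sample the closed-form fields (the fixture's
    ground truth); ``analytic_sdf=False`` samples the triangle meshes
    instead, exercising the full mesh-to-field path at the cost of the
    meshes' faceting error.
    """
    if r_ball <= 0 or clearance < 0:
        raise InvalidInputError("radii must be positive")
    if coverage_deg <= 0 or coverage_deg > 360:
        raise InvalidInputError("coverage_deg must be in (0, 360]")
    r_socket = r_ball + clearance
    ball = trimesh.creation.icosphere(subdivisions=subdivisions,
                                      radius=r_ball)
    if coverage_deg >= 360.0:
        socket = trimesh.creation.icosphere(subdivisions=subdivisions,
                                            radius=r_socket)
        socket.invert()
        articular = np.arange(len(ball.vertices))
    else:
        socket = _socket_shell(r_socket, 0.15 * r_socket, coverage_deg)
        # ball cap facing the socket opening direction (-Z interior)
        coslim = np.cos(np.radians(180.0 - coverage_deg / 2.0))
        z_hat = np.asarray(ball.vertices)[:, 2] / r_ball
        articular = np.flatnonzero(z_hat <= coslim)
    socket_fn = lambda p: r_socket - np.linalg.norm(np.atleast_2d(p),
                                                    axis=-1)
    ball_fn = lambda p: np.linalg.norm(np.atleast_2d(p), axis=-1) - r_ball
    if analytic_sdf and coverage_deg >= 360.0:
        sdf = build_sdf_from_function(socket_fn, (0.0, 0.0, 0.0),
                                      1.5 * r_socket, sdf_resolution)
    else:
        sdf = build_sdf(socket, (0.0, 0.0, 0.0), 1.5 * r_socket,
                        sdf_resolution)
    distal_sdf = None
    if with_distal_sdf:
        if analytic_sdf:
            distal_sdf = build_sdf_from_function(
                ball_fn, (0.0, 0.0, 0.0), 1.5 * r_socket, sdf_resolution)
        else:
            distal_sdf = build_sdf(ball, (0.0, 0.0, 0.0), 1.5 * r_socket,
                                   sdf_resolution)
    joint = JointModel(proximal_mesh=socket, proximal_sdf=sdf,
                       distal_mesh=ball, articular_vertices=articular,
                       d_t=clearance, distal_sdf=distal_sdf)
    return joint, {"socket_sdf": socket_fn, "ball_sdf": ball_fn}


def _heightfield_solid(xs: np.ndarray, ys: np.ndarray, z_top, z_bottom
                       ) -> tuple[trimesh.Trimesh, dict]:
    """Watertight solid between two height fields over a rectangular patch.

    ``z_top``/``z_bottom`` are callables of (X, Y) grids or constants.
    Returns the mesh and the vertex index ranges of the two surfaces.
    """
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nx, ny = X.shape
    Zt = z_top(X, Y) if callable(z_top) else z_top
    Zb = z_bottom(X, Y) if callable(z_bottom) else z_bottom
    Zt = np.broadcast_to(np.asarray(Zt, float), X.shape)
    Zb = np.broadcast_to(np.asarray(Zb, float), X.shape)
    if np.any(Zb >= Zt):
        raise InvalidInputError("bottom surface must stay below top surface")
    top = np.stack([X, Y, Zt], axis=-1).reshape(-1, 3)
    bot = np.stack([X, Y, Zb], axis=-1).reshape(-1, 3)
    verts = np.concatenate([top, bot])
    off = nx * ny

    def tid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = tid(i, j), tid(i + 1, j), tid(i, j + 1), \
                tid(i + 1, j + 1)
            faces += [[a, b, d], [a, d, c]]                 # top (+z)
            faces += [[off + a, off + d, off + b],
                      [off + a, off + c, off + d]]          # bottom (-z)

    # walls, subdivided vertically into strips of roughly cell-sized quads
    # (keeps triangle bounding radii uniform for the closest-point search)
    verts = [verts]
    n_verts = 2 * nx * ny
    cell = float(min(np.diff(xs).min(), np.diff(ys).min()))
    n_layers = max(1, int(np.ceil((Zt - Zb).max() / cell)))

    def wall(boundary_ids):
        """Quad-strip wall between bottom and top along a boundary loop."""
        nonlocal n_verts
        topv = np.concatenate(verts)[boundary_ids]
        botv = np.concatenate(verts)[off + boundary_ids]
        rows = [off + boundary_ids]  # t = 0: bottom boundary vertices
        for k in range(1, n_layers):
            t = k / n_layers
            ring = (1 - t) * botv + t * topv
            verts.append(ring)
            rows.append(n_verts + np.arange(len(ring)))
            n_verts += len(ring)
        rows.append(boundary_ids)  # t = 1: top boundary vertices
        for r0, r1 in zip(rows[:-1], rows[1:]):
            for a, b, c, d in zip(r0[:-1], r0[1:], r1[:-1], r1[1:]):
                faces.extend([[a, b, d], [a, d, c]])

    # boundary loop ids, oriented so each wall is built once
    wall(np.array([tid(i, 0) for i in range(nx)]))
    wall(np.array([tid(nx - 1, j) for j in range(ny)]))
    wall(np.array([tid(i, ny - 1) for i in range(nx)])[::-1])
    wall(np.array([tid(0, j) for j in range(ny)])[::-1])

    # adjacent walls duplicate their shared corner columns: merge exact
    # duplicates while keeping track of the surface vertex indices
    allv = np.concatenate(verts)
    uniq, inv = np.unique(allv, axis=0, return_inverse=True)
    mesh = trimesh.Trimesh(vertices=uniq, faces=inv[np.array(faces)],
                           process=False)
    trimesh.repair.fix_normals(mesh)
    info = {"top": inv[np.arange(nx * ny)],
            "bottom": inv[off + np.arange(nx * ny)]}
    return mesh, info


def make_hemisellar(radius_x: float = 40.0, radius_y: float = -32.0,
                    half_width: float = 6.0, counter_half_width: float = 3.0,
                    gap: float = 0.4, grid_n: int = 21, depth: float = 5.0,
                    sdf_resolution: int = 41) -> JointModel:
    """Saddle joint: concave-convex articular patch plus congruent cap.

    ``radius_x``/``radius_y`` are the principal radii of curvature of the
    saddle (mm) and must have opposite signs.  The distal cap's underside
    is the saddle offset by ``gap`` over a smaller footprint, so the mean
    joint proximity at the reference pose is ~``gap``.  Both meshes are
    mirror-symmetric about the x = 0 (and y = 0) planes.
    """
    if radius_x * radius_y >= 0:
        raise InvalidInputError(
            "saddle needs principal curvatures of opposite sign")
    if gap < 0 or half_width <= 0 or counter_half_width >= half_width:
        raise InvalidInputError("invalid saddle dimensions")

    def saddle(X, Y):
        return X ** 2 / (2 * radius_x) + Y ** 2 / (2 * radius_y)

    xs = np.linspace(-half_width, half_width, grid_n)
    prox, _ = _heightfield_solid(
        xs, xs, saddle, -depth - half_width ** 2 / (2 * abs(radius_y)))
    xs2 = np.linspace(-counter_half_width, counter_half_width, grid_n)
    dist, dinfo = _heightfield_solid(
        xs2, xs2, lambda X, Y: gap + depth / 2.0,
        lambda X, Y: gap + saddle(X, Y))
    half_extent = 1.6 * half_width
    sdf = build_sdf(prox, (0.0, 0.0, 0.0), half_extent, sdf_resolution)
    return JointModel(proximal_mesh=prox, proximal_sdf=sdf, distal_mesh=dist,
                      articular_vertices=dinfo["bottom"], d_t=gap)


def make_cylinder_obstacle(radius: float = 0.5, center=(0.0, 0.0, 0.0),
                           half_extent: float = 3.0, resolution: int = 61):
    """Analytic infinite-cylinder obstacle (axis along Z) sampled as a grid.

    Returns ``(grid, mesh, analytic_sdf)``; the taut-string geodesic
    around the cylinder has a closed form used as a test oracle.
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    center = np.asarray(center, float)

    def analytic(p):
        q = np.atleast_2d(p) - center
        return np.sqrt(q[:, 0] ** 2 + q[:, 1] ** 2) - radius

    grid = build_sdf_from_function(analytic, center, half_extent, resolution)
    mesh = trimesh.creation.cylinder(radius=radius,
                                     height=2.0 * half_extent)
    mesh.apply_translation(center)
    return grid, mesh, analytic


def make_ligament_set(joint: JointModel, n_ligaments: int = 6, seed: int = 0,
                      n_segments: int = 20,
                      config: PathConfig | None = None) -> list[Ligament]:
    """Deterministic ligament attachments with reference-pose rest lengths.

    Origins are sampled on the proximal mesh surface and insertions on the
    distal mesh surface (well-separated vertices, fixed by the seed); each
    rest length equals the solved wrapped-path length at the all-zero
    reference pose, so reference-pose strains are zero by construction.
    """
    if not 1 <= n_ligaments <= len(LIGAMENT_NAMES):
        raise InvalidInputError(
            f"n_ligaments must be in [1, {len(LIGAMENT_NAMES)}]")
    rng = np.random.default_rng(seed)
    prox_v = np.asarray(joint.proximal_mesh.vertices)
    dist_v = np.asarray(joint.distal_mesh.vertices)
    # candidate attachment sites lie near the joint (within ~2 articular
    # radii of the articular centroid), as capsular ligaments do; the
    # picks are spread by greedy farthest-point from a seeded start and
    # offset slightly off the surface
    art = joint.articular_points
    c, r = art.mean(axis=0), joint.articular_radius()
    near_p = np.flatnonzero(np.linalg.norm(prox_v - c, axis=1) < 2.2 * r)
    near_d = np.flatnonzero(np.linalg.norm(dist_v - c, axis=1) < 2.2 * r)
    if len(near_p) < n_ligaments:
        near_p = np.arange(len(prox_v))
    if len(near_d) < n_ligaments:
        near_d = np.arange(len(dist_v))
    ligaments = []
    prox_idx = near_p[_spread_indices(prox_v[near_p], n_ligaments, rng)]
    dist_idx = near_d[_spread_indices(dist_v[near_d], n_ligaments, rng)]
    pn = np.asarray(joint.proximal_mesh.vertex_normals)
    dn = np.asarray(joint.distal_mesh.vertex_normals)
    lift = 0.05 * r  # attach just off the surface, along the outward normal
    for k in range(n_ligaments):
        origin = prox_v[prox_idx[k]] + lift * pn[prox_idx[k]]
        insertion = dist_v[dist_idx[k]] + lift * dn[dist_idx[k]]
        lig = Ligament(name=LIGAMENT_NAMES[k], origin=origin,
                       insertion=insertion, rest_length=1.0,
                       n_segments=n_segments)
        length, conv = path_length_for_pose(joint, lig, Pose(0, 0, 0),
                                            config)
        ligaments.append(Ligament(name=lig.name, origin=origin,
                                  insertion=insertion, rest_length=length,
                                  n_segments=n_segments))
    return ligaments


def _spread_indices(verts: np.ndarray, k: int, rng) -> np.ndarray:
    start = int(rng.integers(len(verts)))
    chosen = [start]
    d = np.linalg.norm(verts - verts[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(verts - verts[nxt], axis=1))
    return np.array(chosen)


def make_trajectory(center=(0.0, 0.0, 0.0), amplitude=(40.0, 25.0, 30.0),
                    n_frames: int = 300, noise_sd: float = 0.0,
                    translation_amplitude: float = 0.3,
                    seed: int = 0) -> pd.DataFrame:
    """Smooth band-limited pose trajectory emulating a manipulation trial.

    Each rotational channel is a sum of three low-frequency sinusoids with
    seeded random phases, scaled to the requested amplitude about
    ``center``; translations are small sinusoids of amplitude
    ``translation_amplitude`` (mm).  Gaussian noise of ``noise_sd`` deg/mm
    is added on top.  Frame-to-frame rotation steps are bounded by
    ``2 * pi * 3 * amplitude / n_frames`` per channel.
    """
    if n_frames < 2:
        raise InvalidInputError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_frames)
    cols = {}
    for name, c, a in zip(("fe", "abad", "lar"), center, amplitude):
        phases = rng.uniform(0, 2 * np.pi, 3)
        weights = np.array([1.0, 0.5, 0.25])
        sig = sum(w * np.sin(2 * np.pi * (k + 1) * t + ph)
                  for k, (w, ph) in enumerate(zip(weights, phases)))
        sig = a * sig / np.abs(sig).max()
        cols[name] = c + sig + rng.normal(0.0, noise_sd, n_frames)
    for name in ("tx", "ty", "tz"):
        ph = rng.uniform(0, 2 * np.pi)
        cols[name] = translation_amplitude * np.sin(2 * np.pi * t + ph) \
            + rng.normal(0.0, noise_sd * 0.01, n_frames)
    return pd.DataFrame(cols)
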