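"""Rotational pose lattices, rigid transforms and the sine-corrected space.

A joint pose is three Euler rotations — flexion/extension (FE),
abduction/adduction (ABAD) and long-axis rotation (LAR), in degrees —
plus three translations (mm) of the distal frame origin expressed in the
proximal joint frame.  Rotations are applied intrinsically in the order
FE about z, then ABAD about y, then LAR about x.

For volume comparison, poses are mapped into an area-corrected "two
neutral" spherical space in which FE- and LAR-displacements are scaled by
the cosine of the elevation (ABAD).  This keeps Euclidean distances and
alpha-shape volumes meaningful near the poles, where raw Euler coordinates
grossly overweight azimuthal motion.  The mapping is pluggable
(:func:`sine_correct` is the default) so an alternative published
transformation can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidInputError

__all__ = ["Pose", "PoseGrid", "generate_pose_grid", "pose_to_transform",
           "sine_correct", "sine_correct_inverse",
           "DEFAULT_RANGES", "DEFAULT_STEP"]

#: Full rotational search ranges (deg): FE and LAR over a full turn with
#: both endpoints retained, ABAD over the open hemisphere.
DEFAULT_RANGES = {"fe": (-180.0, 180.0), "abad": (-90.0, 90.0),
                  "lar": (-180.0, 180.0)}
DEFAULT_STEP = 5.0


@dataclass(frozen=True)
class Pose:
    """One joint pose: Euler rotations in degrees, translations in mm."""

    fe: float
    abad: float
    lar: float
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.fe, self.abad, self.lar])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])


@dataclass
class PoseGrid:
    """Inclusive rotational lattice in row-major FE -> ABAD -> LAR order."""

    ranges: dict
    step: float
    angles: np.ndarray = field(repr=False)  # (n, 3) fe, abad, lar in deg
    axis_values: tuple = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.angles)

    def __iter__(self):
        for fe, abad, lar in self.angles:
            yield Pose(fe=fe, abad=abad, lar=lar)

    @property
    def poses(self) -> list:
        return list(self)

    @property
    def shape(self) -> tuple:
        return tuple(len(v) for v in self.axis_values)


def _axis_lattice(lo: float, hi: float, step: float, name: str) -> np.ndarray:
    if step <= 0:
        raise InvalidInputError(f"{name}: step must be positive")
    if lo >= hi:
        raise InvalidInputError(f"{name}: range minimum must be below maximum")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidInputError(
            f"{name}: step {step} does not divide the range [{lo}, {hi}] — "
            "refusing to truncate the lattice silently")
    return lo + step * np.arange(int(round(n_steps)) + 1)


def generate_pose_grid(ranges: dict | None = None,
                       step: float = DEFAULT_STEP) -> PoseGrid:
    """Build the inclusive rotational lattice.

    With the default ranges and 5-deg step this yields 73 x 37 x 73 =
    197,173 orientations.  FE/LAR endpoints at -180 and +180 deg describe
    the same physical rotation but are both kept, so lattice counts follow
    the inclusive-endpoint convention.
    """
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    fe = _axis_lattice(*ranges["fe"], step, "fe")
    abad = _axis_lattice(*ranges["abad"], step, "abad")
    lar = _axis_lattice(*ranges["lar"], step, "lar")
    if np.max(np.abs(abad)) > 90 + 1e-9:
        raise InvalidInputError("lattice ABAD values must satisfy |abad| <= 90")
    F, A, L = np.meshgrid(fe, abad, lar, indexing="ij")
    angles = np.stack([F, A, L], axis=-1).reshape(-1, 3)
    return PoseGrid(ranges=ranges, step=step, angles=angles,
                    axis_values=(fe, abad, lar))


def _check_frame(frame: np.ndarray, name: str) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (4, 4):
        raise InvalidInputError(f"{name} must be a 4x4 homogeneous transform")
    R = frame[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise InvalidInputError(f"{name} rotation must be right-handed orthonormal")
    return frame


def rotation_matrix(fe: float, abad: float, lar: float) -> np.ndarray:
    """Intrinsic z-y-x rotation for (FE, ABAD, LAR) in degrees."""
    return Rotation.from_euler("ZYX", [fe, abad, lar],
                               degrees=True).as_matrix()


def pose_to_transform(pose: Pose, proximal_frame=None,
                      distal_frame=None) -> np.ndarray:
    """Rigid transform mapping distal-bone coordinates to proximal-bone ones.

    ``proximal_frame`` is the joint frame expressed in the proximal bone
    (4x4); ``distal_frame`` is the same joint frame expressed in the distal
    bone at the reference pose.  Translations are expressed in the proximal
    joint frame, so the translational search domain does not rotate with
    the pose.  The all-zero pose maps the distal reference pose onto itself.
    """
    P = _check_frame(np.eye(4) if proximal_frame is None else proximal_frame,
                     "proximal_frame")
    D = _check_frame(np.eye(4) if distal_frame is None else distal_frame,
                     "distal_frame")
    J = np.eye(4)
    J[:3, :3] = rotation_matrix(pose.fe, pose.abad, pose.lar)
    J[:3, 3] = pose.translation
    return P @ J @ np.linalg.inv(D)


def sine_correct(angles) -> np.ndarray:
    """Map (fe, abad, lar) degrees into the sine-corrected space.

    ``fe_sc = fe * cos(abad)``, ``lar_sc = lar * cos(abad)``,
    ``abad_sc = abad``: an equal-area-style elevation scaling, invertible
    for ``|abad| < 90`` and the identity at the equator.  This is the
    default stand-in mapping; any fixed area-corrected map preserves the
    two properties the pipeline relies on (nearest-neighbour structure and
    volumes).
    """
    a = np.atleast_2d(np.asarray(angles, dtype=float))
    if np.any(np.abs(a[:, 1]) > 90 + 1e-9):
        raise InvalidInputError("sine correction requires |abad| <= 90 deg")
    c = np.cos(np.radians(a[:, 1]))
    out = np.stack([a[:, 0] * c, a[:, 1], a[:, 2] * c], axis=-1)
    return out if np.ndim(angles) > 1 else out[0]


def sine_correct_inverse(corrected) -> np.ndarray:
    """Invert :func:`sine_correct` (defined for ``|abad| < 90``)."""
    a = np.atleast_2d(np.asarray(corrected, dtype=float))
    if np.any(np.abs(a[:, 1]) >= 90):
        raise InvalidInputError("inverse undefined at |abad| >= 90 deg")
    c = np.cos(np.radians(a[:, 1]))
    out = np.stack([a[:, 0] / c, a[:, 1], a[:, 2] / c], axis=-1)
    return out if np.ndim(corrected) > 1 else out[0]
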