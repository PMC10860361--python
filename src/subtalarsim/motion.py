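"""Simulated subtalar motions and bone-impingement validation.

Two single-axis motions are simulated, mirroring how hindfoot kinematics are
commonly idealised as rigid helical-axis rotations:

* inversion/eversion: rotation of the talus about the subtalar rotation axis,
  by default 9 degrees of inversion to 9 degrees of eversion in 3-degree
  steps (7 positions including neutral);
* internal/external peritalar rotation (the subluxation motion seen in
  progressive collapsing foot deformity): rotation of the talus about a
  vertical axis through the talocrural axis midpoint, same 9/3 protocol.

The talus moves and the calcaneus stays fixed; only relative motion affects
ligament length.  Positive angles are inversion / internal rotation by the
right-hand rule about the axis direction.

The range of motion is chosen to be impingement-free; the impingement check
here validates that choice rather than clamping the motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError, GeometryError
from .geometry import RotationAxis, SurfaceMesh, rotate_about_axis

INVERSION_EVERSION = "inversion_eversion"
INTERNAL_EXTERNAL = "internal_external"

#: sub-resolution penetration that is not reported as contact (mm)
CONTACT_TOL = 0.05


@dataclass(frozen=True)
class MotionProtocol:
    """One motion: axis, half-range and angular step (degrees)."""

    motion_type: str
    axis: RotationAxis
    max_angle: float = 9.0
    step: float = 3.0

    def __post_init__(self):
        if self.motion_type not in (INVERSION_EVERSION, INTERNAL_EXTERNAL):
            raise ConfigError(f"unknown motion type {self.motion_type!r}")
        if self.max_angle <= 0 or self.step <= 0:
            raise ConfigError("max_angle and step must be positive")
        ratio = self.max_angle / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"max_angle ({self.max_angle}) must be divisible by step ({self.step})"
            )


@dataclass(frozen=True)
class MotionPosition:
    """A signed angle along one motion; alpha = 0 is neutral."""

    angle: float
    motion_type: str
    axis: RotationAxis = field(compare=False, default=None)


def enumerate_positions(protocol: MotionProtocol) -> list[MotionPosition]:
    """Ordered positions -max ... -step, 0, +step ... +max.

    Length is 2*(max/step) + 1: seven positions per motion at the default
    9-degree half-range with 3-degree increments.
    """
    n = round(protocol.max_angle / protocol.step)
    angles = [i * protocol.step for i in range(-n, n + 1)]
    return [MotionPosition(angle=a, motion_type=protocol.motion_type, axis=protocol.axis) for a in angles]


def apply_motion(obj, position: MotionPosition):
    """Rotate talus-side geometry (points or a SurfaceMesh) to a position.

    Neutral (alpha = 0) returns an identical copy.  The calcaneus is, by
    convention, never transformed.
    """
    if position.axis is None:
        raise ConfigError("motion position carries no axis")
    if isinstance(obj, SurfaceMesh):
        return obj.transformed(lambda v: rotate_about_axis(v, position.axis, position.angle))
    return rotate_about_axis(np.asarray(obj, float), position.axis, position.angle)


@dataclass
class ImpingementReport:
    """Outcome of a surface-interpenetration check at one position."""

    contact: bool
    max_penetration: float  # mm, >= 0
    contact_points: np.ndarray  # (k, 3) talus vertices inside the calcaneus
    angle: float = 0.0
    motion_type: str = ""

    def to_dict(self) -> dict:
        return {
            "contact": bool(self.contact),
            "max_penetration_mm": float(self.max_penetration),
            "n_contact_points": int(len(self.contact_points)),
            "angle_deg": float(self.angle),
            "motion_type": self.motion_type,
        }


def detect_impingement(
    talus: SurfaceMesh,
    calcaneus: SurfaceMesh,
    position: MotionPosition | None = None,
    tol: float = CONTACT_TOL,
) -> ImpingementReport:
    """Report talus-calcaneus surface interpenetration at a motion position.

    A talus vertex is inside the calcaneus when a ray-crossing parity test
    against the watertight calcaneal surface says so and its distance to
    that surface exceeds ``tol`` (sub-resolution overlaps are not reported).
    A nearest-vertex KDTree prefilter keeps the exact parity test to the few
    vertices close enough to the calcaneus to possibly penetrate.
    """
    from .geometry import _ray_triangle_distances

    for m, name in ((talus, "talus"), (calcaneus, "calcaneus")):
        if not m.is_watertight:
            raise GeometryError(f"{name} mesh is not watertight; impingement check undefined")
    pts = talus.vertices
    if position is not None and position.angle != 0.0:
        pts = apply_motion(pts, position)
    tree = cKDTree(calcaneus.vertices)
    near_dist, _ = tree.query(pts)
    # candidates: closer to the calcaneal surface than one mesh edge length
    edge = float(np.median(calcaneus.as_trimesh().edges_unique_length))
    cand = np.flatnonzero(near_dist < 2.0 * edge)
    tri = calcaneus.vertices[calcaneus.faces]
    probe = np.array([0.5773502691896258, 0.5773502691896257, 0.5773502691896259])
    inside_idx = []
    depths = []
    for i in cand:
        t, mask = _ray_triangle_distances(pts[i], probe, tri)
        crossings = int(np.count_nonzero(mask & (t > 0.0)))
        if crossings % 2 == 1 and near_dist[i] > tol:
            inside_idx.append(i)
            depths.append(near_dist[i])
    inside_idx = np.asarray(inside_idx, dtype=int)
    return ImpingementReport(
        contact=bool(inside_idx.size),
        max_penetration=float(max(depths)) if depths else 0.0,
        contact_points=pts[inside_idx] if inside_idx.size else np.empty((0, 3)),
        angle=0.0 if position is None else position.angle,
        motion_type="" if position is None else position.motion_type,
    )


def check_protocol_clearance(
    talus: SurfaceMesh,
    calcaneus: SurfaceMesh,
    protocols: list[MotionProtocol],
    tol: float = CONTACT_TOL,
) -> list[ImpingementReport]:
    """Impingement reports at every position of every protocol (validation
    that the configured range of motion is impingement-free)."""
    reports = []
    for proto in protocols:
        for pos in enumerate_positions(proto):
            reports.append(detect_impingement(talus, calcaneus, pos, tol=tol))
    return reports
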