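"""Core geometric primitives: meshes, landmark sets, sphere fitting, rotation
axes, rigid rotations and ray-mesh intersection.

Everything downstream (motion simulation, tunnel placement, strain profiles)
is built on the operations in this module.  The coordinate frame is the
canonical right-foot frame: right-handed, +X lateral, +Y anterior, +Z
proximal, units millimetres.  Left-sided specimens are mirrored about the
sagittal (YZ) plane at generation or import time.

The subtalar rotation axis is constructed as the line joining the centers of
two least-squares spheres: one fitted to landmarks on the posterior talar
facet of the calcaneus, one fitted to landmarks on the (surrogate) navicular
facet of the talar head.  Rotating the talus about this line models
inversion/eversion as a single-axis ball-joint motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import trimesh
from scipy.optimize import least_squares

from .errors import DegenerateInputError, GeometryError

# Canonical frame unit vectors (right foot).
LATERAL = np.array([1.0, 0.0, 0.0])
ANTERIOR = np.array([0.0, 1.0, 0.0])
PROXIMAL = np.array([0.0, 0.0, 1.0])

#: hits closer than this to a ray origin are discarded (origin on the surface)
RAY_SELF_INTERSECT_TOL = 1e-9


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[-1] != 3:
        raise ValueError(f"expected 3-vectors, got shape {pts.shape}")
    return pts


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateInputError("cannot normalize a (near-)zero vector")
    return v / n


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMesh:
    """Closed triangle surface mesh of one bone (millimetres).

    ``face_labels`` are integer codes per face: 0 = non-articular,
    positive = articular facet id (1 = posterior talocalcaneal facet,
    2 = navicular facet of the talar head).
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None
    side: str = "right"
    name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.face_labels is not None:
            self.face_labels = np.ascontiguousarray(self.face_labels, dtype=np.int64)
            if len(self.face_labels) != len(self.faces):
                raise ValueError("face_labels length mismatch")
        self._trimesh: trimesh.Trimesh | None = None

    # trimesh is the backing container for IO, watertightness and ray casting
    def as_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, **kw) -> "SurfaceMesh":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces), **kw)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def articular_mask(self) -> np.ndarray:
        if self.face_labels is None:
            return np.zeros(len(self.faces), dtype=bool)
        return self.face_labels > 0

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            face_labels=None if self.face_labels is None else self.face_labels.copy(),
            side=self.side,
            name=self.name,
        )

    def transformed(self, fn) -> "SurfaceMesh":
        """Return a copy with ``fn`` applied to the vertex array."""
        out = self.copy()
        out.vertices = np.asarray(fn(self.vertices), dtype=float)
        return out

    def mirrored(self) -> "SurfaceMesh":
        """Mirror about the sagittal (YZ) plane, flipping winding to keep
        outward orientation."""
        out = self.copy()
        out.vertices = self.vertices * np.array([-1.0, 1.0, 1.0])
        out.faces = self.faces[:, ::-1].copy()
        out.side = "left" if self.side == "right" else "right"
        return out


@dataclass
class LandmarkSet:
    """Named reference points grouped by articular facet.

    ``groups`` maps a facet name (``calcaneal_posterior_facet``,
    ``navicular_facet``) to a (k, 3) array of points; ``points`` holds single
    named landmarks such as the medial/lateral trochlear centers used for the
    talocrural axis.
    """

    groups: dict
    points: dict = field(default_factory=dict)

    CALCANEAL = "calcaneal_posterior_facet"
    NAVICULAR = "navicular_facet"

    def __post_init__(self):
        self.groups = {k: _as_points(v) for k, v in self.groups.items()}
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}

    def group(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise DataKeyError(name)
        return self.groups[name]

    def mirrored(self) -> "LandmarkSet":
        m = np.array([-1.0, 1.0, 1.0])
        return LandmarkSet(
            groups={k: v * m for k, v in self.groups.items()},
            points={k: v * m for k, v in self.points.items()},
        )


class DataKeyError(DegenerateInputError, KeyError):
    def __init__(self, name):
        super().__init__(f"landmark group or point {name!r} is missing")


@dataclass
class RotationAxis:
    """A line in space (point + unit direction) with a signed-angle convention.

    Positive angles follow the right-hand rule about ``direction``.  The tag
    records the convention: ``inversion_positive`` for the subtalar axis,
    ``internal_rotation_positive`` for the vertical subluxation axis,
    ``medial_to_lateral`` for the talocrural axis.
    """

    point: np.ndarray
    direction: np.ndarray
    convention: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise DegenerateInputError("axis direction is a zero vector")
            self.direction = self.direction / n
        # after normalisation the unit invariant holds to 1e-12
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-12

    def mirrored(self) -> "RotationAxis":
        m = np.array([-1.0, 1.0, 1.0])
        meta = dict(self.meta)
        if "segment" in meta:
            a, b = meta["segment"]
            meta["segment"] = (np.asarray(a) * m, np.asarray(b) * m)
        return RotationAxis(self.point * m, self.direction * m, self.convention, meta)

    def perpendicular_distance(self, p) -> np.ndarray:
        """Perpendicular distance of point(s) ``p`` to the axis line."""
        rel = _as_points(p) - self.point
        along = rel @ self.direction
        perp = rel - np.outer(along, self.direction)
        d = np.linalg.norm(perp, axis=-1)
        return d if d.size > 1 else float(d[0])

    def to_dict(self) -> dict:
        return {
            "point": self.point.tolist(),
            "direction": self.direction.tolist(),
            "convention": self.convention,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RotationAxis":
        return cls(np.asarray(d["point"]), np.asarray(d["direction"]), d.get("convention", ""))


@dataclass
class FittedSphere:
    """Least-squares sphere with its RMS point-to-surface residual."""

    center: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if not self.radius > 0:
            raise DegenerateInputError("fitted sphere has non-positive radius")
        if self.rms_residual < 0:
            raise ValueError("negative residual")


class RayHit(NamedTuple):
    point: np.ndarray
    face_index: int
    distance: float


# ---------------------------------------------------------------------------
# Sphere fitting and axis construction
# ---------------------------------------------------------------------------


def fit_sphere(points: Sequence, *, tol: float = 1e-10, max_iter: int = 100) -> FittedSphere:
    """Least-squares sphere through >=4 non-coplanar points.

    An algebraic (Pratt-style) linear solve provides the initial estimate;
    a geometric Gauss-Newton refinement of sum((|p - c| - r)^2) follows.  The
    fit interpolates exactly when the points lie exactly on a sphere.
    """
    pts = _as_points(points)
    if len(pts) < 4:
        raise DegenerateInputError(f"sphere fit needs >=4 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] <= max(1e-12, 1e-8 * svals[0]):
        raise DegenerateInputError("points are (near-)coplanar; sphere fit is degenerate")

    # algebraic: |p|^2 = 2 p.c + (r^2 - |c|^2)
    a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("algebraic sphere fit collapsed (non-positive radius)")
    radius = float(np.sqrt(r2))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    res = least_squares(
        resid,
        x0=np.append(center, radius),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 5,
    )
    center, radius = res.x[:3], float(res.x[3])
    if radius <= 0:
        raise DegenerateInputError("sphere fit converged to non-positive radius")
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return FittedSphere(center=center, radius=radius, rms_residual=rms)


def estimate_subtalar_axis(landmarks: LandmarkSet) -> RotationAxis:
    """Subtalar rotation axis from facet landmarks.

    Fits one sphere to the calcaneal posterior-facet group and one to the
    navicular-facet group; the axis runs through the calcaneal sphere center
    toward the navicular sphere center.  Both fitted spheres are kept as
    provenance in ``axis.meta``.
    """
    s_calc = fit_sphere(landmarks.group(LandmarkSet.CALCANEAL))
    s_nav = fit_sphere(landmarks.group(LandmarkSet.NAVICULAR))
    delta = s_nav.center - s_calc.center
    if np.linalg.norm(delta) < 1e-6:
        raise DegenerateInputError(
            "facet sphere centers coincide; subtalar axis is undefined"
        )
    return RotationAxis(
        point=s_calc.center,
        direction=_unit(delta),
        convention="inversion_positive",
        meta={"calcaneal_sphere": s_calc, "navicular_sphere": s_nav},
    )


def estimate_talocrural_axis(medial, lateral=None) -> RotationAxis:
    """Talocrural (ankle flexion) axis through the medial and lateral
    trochlear center landmarks, direction medial -> lateral.

    Accepts either two points or a :class:`LandmarkSet` containing
    ``trochlea_medial`` / ``trochlea_lateral``.
    """
    if isinstance(medial, LandmarkSet):
        lm = medial
        try:
            medial = lm.points["trochlea_medial"]
            lateral = lm.points["trochlea_lateral"]
        except KeyError as exc:
            raise DataKeyError(str(exc)) from exc
    if lateral is None:
        raise DegenerateInputError("talocrural axis needs two landmark points")
    medial = np.asarray(medial, dtype=float)
    lateral = np.asarray(lateral, dtype=float)
    if np.linalg.norm(lateral - medial) < 1e-9:
        raise DegenerateInputError("trochlear landmarks coincide")
    return RotationAxis(
        point=medial,
        direction=_unit(lateral - medial),
        convention="medial_to_lateral",
        meta={"segment": (medial.copy(), lateral.copy())},
    )


def make_vertical_axis(talocrural: RotationAxis) -> RotationAxis:
    """Vertical subluxation axis: +Z line through the midpoint of the
    talocrural landmark segment.  Positive angle = internal talar rotation
    (right-hand rule about +Z moves anterior toward medial on a right foot).
    """
    if "segment" in talocrural.meta:
        a, b = talocrural.meta["segment"]
        point = 0.5 * (np.asarray(a) + np.asarray(b))
    else:
        point = talocrural.point
    return RotationAxis(
        point=point, direction=PROXIMAL.copy(), convention="internal_rotation_positive"
    )


# ---------------------------------------------------------------------------
# Rigid rotation
# ---------------------------------------------------------------------------


def rotation_matrix(direction, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit direction (right-hand rule)."""
    k = _unit(direction)
    theta = np.deg2rad(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1.0 - np.cos(theta)) * (kx @ kx)


def rotate_about_axis(p, axis: RotationAxis, angle_deg: float) -> np.ndarray:
    """Rotate point(s) ``p`` by ``angle_deg`` about the axis line.

    A zero angle returns the input exactly (no floating-point round trip
    through the axis point)."""
    if angle_deg == 0.0:
        return np.array(p, dtype=float)
    rot = rotation_matrix(axis.direction, angle_deg)
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = (pts - axis.point) @ rot.T + axis.point
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Ray-mesh intersection
# ---------------------------------------------------------------------------


def _ray_triangle_distances(origin, direction, triangles, eps: float = 1e-12):
    """Vectorised Möller-Trumbore: signed ray parameters for one ray against
    an (m, 3, 3) triangle array.  Returns (t, mask) where ``mask`` marks
    triangles the ray actually crosses (barycentric coordinates in range,
    non-parallel)."""
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin[None, :] - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    mask = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps)
    return t, mask


def intersect_ray_mesh(origin, direction, mesh: SurfaceMesh) -> list[RayHit]:
    """All intersections of a ray with a mesh, sorted by distance.

    Uses a vectorised Möller-Trumbore test over every triangle.  Hits closer
    than 1e-9 mm to the origin are discarded so that rays anchored on the
    surface do not report their own origin; duplicate hits on shared
    triangle edges are merged.  An empty list is a valid outcome.
    """
    origin = np.asarray(origin, dtype=float)
    direction = _unit(direction)
    tri = mesh.vertices[mesh.faces]
    t, mask = _ray_triangle_distances(origin, direction, tri)
    mask = mask & (t > RAY_SELF_INTERSECT_TOL)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    order = idx[np.argsort(t[idx], kind="stable")]
    hits: list[RayHit] = []
    for i in order:
        d = float(t[i])
        if hits and abs(d - hits[-1].distance) < 1e-7:
            continue  # duplicate hit on a shared edge/vertex
        hits.append(RayHit(point=origin + d * direction, face_index=int(i), distance=d))
    return hits


def intersect_line_mesh(axis: RotationAxis, mesh: SurfaceMesh, span: float = 500.0) -> list[tuple]:
    """Intersections of the full (two-sided) axis line with a mesh.

    Returns ``(t, point, face_index)`` tuples sorted by the signed line
    parameter ``t`` (mm along ``axis.direction`` from ``axis.point``).
    """
    origin = axis.point - span * axis.direction
    hits = intersect_ray_mesh(origin, axis.direction, mesh)
    out = [(h.distance - span, h.point, h.face_index) for h in hits]
    if any(abs(t) > span * 0.98 for t, _, _ in out):
        raise GeometryError("line-mesh span too small; increase `span`")
    return out
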