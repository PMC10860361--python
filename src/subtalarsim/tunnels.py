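"""Candidate bone-tunnel generation in the subtalar space.

The baseline tunnel on each bone runs along the subtalar rotation axis: the
axis pierces each bone twice, the hit facing the inter-bone gap is the
baseline *exit* (where the ligament graft would emerge into the tarsal
canal) and the opposite cortex hit is the *entry*.  Candidate tunnels are
produced by tilting the baseline direction about the entry point by 2, 4, 6
or 8 degrees in either sense within four deviation planes oriented by the
talocrural axis:

* proximal_distal (positive theta -> distal),
* medial_lateral (positive theta -> lateral),
* lateroproximal_mediodistal (positive theta -> mediodistal),
* medioproximal_laterodistal (positive theta -> laterodistal).

That is 4 planes x 8 signed angles + 1 undeviated ray = 33 exit points per
bone and 33 x 33 = 1089 talar-calcaneal combinations.

Each exit point is classified extra- or intraarticular against the labeled
articular facet faces, with a conservative 0.1 mm boundary tolerance
(points that close to an articular face count as intraarticular).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import DegenerateInputError, GeometryError
from .geometry import (
    RotationAxis,
    SurfaceMesh,
    intersect_line_mesh,
    intersect_ray_mesh,
)

PLANES = (
    "proximal_distal",
    "medial_lateral",
    "lateroproximal_mediodistal",
    "medioproximal_laterodistal",
)

#: (negative-theta pole, positive-theta pole) for each plane
PLANE_POLES = {
    "proximal_distal": ("proximal", "distal"),
    "medial_lateral": ("medial", "lateral"),
    "lateroproximal_mediodistal": ("lateroproximal", "mediodistal"),
    "medioproximal_laterodistal": ("medioproximal", "laterodistal"),
}

DEVIATION_ANGLES = (2.0, 4.0, 6.0, 8.0)

#: exits within this distance of an articular face count as intraarticular
INTRUSION_BOUNDARY_TOL = 0.1


def orientation_label(plane: str | None, theta: float) -> str:
    """Human-readable orientation, e.g. ('medioproximal_laterodistal', +6)
    -> 'laterodistal 6'."""
    if plane is None or theta == 0:
        return "axis 0"
    neg, pos = PLANE_POLES[plane]
    return f"{pos if theta > 0 else neg} {abs(theta):g}"


@dataclass(frozen=True)
class DeviationFrame:
    """Orthonormal frame for tunnel deviations at one bone's entry point.

    ``baseline_direction`` points along the subtalar axis toward the other
    bone; ``lateral`` is the talocrural direction orthogonalised against the
    baseline (positive +X component); ``proximal`` completes the frame
    (positive +Z component where defined).
    """

    origin: np.ndarray
    baseline_direction: np.ndarray
    lateral: np.ndarray
    proximal: np.ndarray

    def in_plane_unit(self, plane: str) -> np.ndarray:
        """Unit vector toward the plane's positive-theta pole."""
        lat, prox = self.lateral, self.proximal
        if plane == "proximal_distal":
            return -prox
        if plane == "medial_lateral":
            return lat
        if plane == "lateroproximal_mediodistal":
            return (-lat - prox) / np.sqrt(2.0)
        if plane == "medioproximal_laterodistal":
            return (lat - prox) / np.sqrt(2.0)
        raise ValueError(f"unknown deviation plane {plane!r}")


@dataclass(frozen=True)
class TunnelRay:
    """One deviated tunnel direction anchored at a bone's entry point."""

    bone: str  # "talus" | "calcaneus"
    plane: str | None  # None for the undeviated baseline ray
    theta: float  # signed degrees, 0 or +-{2,4,6,8}
    direction: np.ndarray = field(compare=False, default=None)


@dataclass
class ExitPoint:
    """Surface intersection of a tunnel ray on the subtalar-space side."""

    bone: str
    ray: TunnelRay
    point: np.ndarray | None
    face_index: int = -1
    intrusion: str | None = None  # "extraarticular" | "intraarticular"
    distance_to_axis_on_surface: float = np.nan
    missed: bool = False

    @property
    def plane(self):
        return self.ray.plane

    @property
    def theta(self):
        return self.ray.theta


@dataclass(frozen=True)
class LigamentCombination:
    """A candidate reconstruction: one talar and one calcaneal exit point."""

    talar_exit: ExitPoint
    calcaneal_exit: ExitPoint
    neutral_length: float

    def __post_init__(self):
        if not self.neutral_length > 0:
            raise DegenerateInputError("combination has non-positive neutral length")


def make_combination(talar_exit: ExitPoint, calcaneal_exit: ExitPoint) -> LigamentCombination:
    if talar_exit.missed or calcaneal_exit.missed:
        raise DegenerateInputError("cannot combine missed exit points")
    l0 = float(np.linalg.norm(talar_exit.point - calcaneal_exit.point))
    return LigamentCombination(talar_exit, calcaneal_exit, l0)


# ---------------------------------------------------------------------------
# Entry / exit construction
# ---------------------------------------------------------------------------


@dataclass
class EntryExitAnchors:
    """Baseline axis-surface intersections for both bones.

    ``t_*`` are signed line parameters along the subtalar axis direction
    (which points from the calcaneal facet sphere center toward the
    navicular one, i.e. from calcaneus to talus across the gap).
    """

    talar_entry: np.ndarray
    talar_exit: np.ndarray
    calcaneal_entry: np.ndarray
    calcaneal_exit: np.ndarray
    t_talar_exit: float
    t_calcaneal_exit: float
    gap_midpoint: np.ndarray
    axis: RotationAxis


def compute_entry_points(
    talus: SurfaceMesh, calcaneus: SurfaceMesh, subtalar_axis: RotationAxis
) -> EntryExitAnchors:
    """Baseline tunnel anchors: intersect the subtalar axis with both bones.

    All axis-mesh hits are ordered along the axis direction; the two hits
    bounding the inter-bone gap are the baseline exits and the outermost hit
    on each bone is its entry.
    """
    hits_t = intersect_line_mesh(subtalar_axis, talus)
    hits_c = intersect_line_mesh(subtalar_axis, calcaneus)
    if len(hits_t) < 2:
        raise GeometryError(
            f"subtalar axis intersects the talus {len(hits_t)} time(s); "
            "expected >=2 (axis misses the bone?)"
        )
    if len(hits_c) < 2:
        raise GeometryError(
            f"subtalar axis intersects the calcaneus {len(hits_c)} time(s); "
            "expected >=2 (axis misses the bone?)"
        )
    # axis direction points calcaneus -> talus: the calcaneal exit is the
    # largest-t calcaneal hit, the talar exit the smallest-t talar hit
    t_c, p_c_exit, _ = max(hits_c, key=lambda h: h[0])
    t_c_in, p_c_entry, _ = min(hits_c, key=lambda h: h[0])
    t_t, p_t_exit, _ = min(hits_t, key=lambda h: h[0])
    t_t_in, p_t_entry, _ = max(hits_t, key=lambda h: h[0])
    if not t_c < t_t:
        raise GeometryError(
            "axis-surface hits do not bound an inter-bone gap "
            f"(calcaneal exit t={t_c:.3f} >= talar exit t={t_t:.3f})"
        )
    mid_t = 0.5 * (t_c + t_t)
    return EntryExitAnchors(
        talar_entry=p_t_entry,
        talar_exit=p_t_exit,
        calcaneal_entry=p_c_entry,
        calcaneal_exit=p_c_exit,
        t_talar_exit=t_t,
        t_calcaneal_exit=t_c,
        gap_midpoint=subtalar_axis.point + mid_t * subtalar_axis.direction,
        axis=subtalar_axis,
    )


def build_deviation_frame(
    entry, subtalar_axis: RotationAxis, talocrural_axis: RotationAxis, toward_other_bone: int = +1
) -> DeviationFrame:
    """Deviation frame at an entry point.

    ``toward_other_bone`` is +1 when the baseline tunnel runs along the
    subtalar axis direction (calcaneal tunnel) and -1 when it runs against
    it (talar tunnel).
    """
    b = subtalar_axis.direction * float(np.sign(toward_other_bone))
    tc = talocrural_axis.direction
    cos_angle = abs(float(np.dot(tc, b)))
    if cos_angle > 1.0 - 5e-13 or np.arccos(min(cos_angle, 1.0)) < 1e-6:
        raise DegenerateInputError(
            "talocrural axis is parallel to the subtalar axis; deviation frame undefined"
        )
    lat = tc - (tc @ b) * b
    lat = lat / np.linalg.norm(lat)
    if lat[0] < 0:
        lat = -lat
    prox = np.cross(lat, b)
    prox = prox / np.linalg.norm(prox)
    if prox[2] < -1e-12:
        prox = -prox
    return DeviationFrame(
        origin=np.asarray(entry, float), baseline_direction=b, lateral=lat, proximal=prox
    )


def enumerate_rays(frame: DeviationFrame, bone: str) -> list[TunnelRay]:
    """The 33 tunnel rays: the baseline plus +-{2,4,6,8} degree tilts in each
    of the four deviation planes (tilt pivots at the entry point)."""
    rays = [TunnelRay(bone=bone, plane=None, theta=0.0, direction=frame.baseline_direction.copy())]
    b = frame.baseline_direction
    for plane in PLANES:
        e = frame.in_plane_unit(plane)
        for mag in DEVIATION_ANGLES:
            for sign in (-1.0, 1.0):
                th = sign * mag
                d = np.cos(np.deg2rad(th)) * b + np.sin(np.deg2rad(th)) * e
                rays.append(
                    TunnelRay(bone=bone, plane=plane, theta=th, direction=d / np.linalg.norm(d))
                )
    return rays


def generate_exit_points(
    mesh: SurfaceMesh,
    frame: DeviationFrame,
    bone: str,
    anchors: EntryExitAnchors,
) -> list[ExitPoint]:
    """Exit points of all 33 rays on one bone.

    Each ray is cast from the entry point; among its surface hits on the
    bone's own side of the inter-bone gap midplane, the last one before the
    ray crosses the midplane is the exit (the point facing the subtalar
    space).  When every hit lies beyond the midplane (strongly deviated rays
    emerging on bone regions that extend past the tarsal canal, e.g. the
    anterior calcaneal process), the first hit - where the ray leaves the
    bone interior - is the exit.  Rays with no surface hit at all are
    flagged as misses rather than raising.
    """
    baseline_exit = anchors.talar_exit if bone == "talus" else anchors.calcaneal_exit
    own_sign = +1.0 if bone == "talus" else -1.0  # side of the midplane along the axis
    u = anchors.axis.direction
    mid = anchors.gap_midpoint
    out: list[ExitPoint] = []
    for ray in enumerate_rays(frame, bone):
        hits = intersect_ray_mesh(frame.origin, ray.direction, mesh)
        if not hits:
            out.append(ExitPoint(bone=bone, ray=ray, point=None, missed=True))
            continue
        own = [h for h in hits if own_sign * float((h.point - mid) @ u) > -1e-6]
        # furthest own-side hit = last before the gap midplane; fall back to
        # the hit where the ray first leaves the bone interior
        h = own[-1] if own else hits[0]
        out.append(
            ExitPoint(
                bone=bone,
                ray=ray,
                point=h.point,
                face_index=h.face_index,
                distance_to_axis_on_surface=float(np.linalg.norm(h.point - baseline_exit)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Intrusion classification
# ---------------------------------------------------------------------------


class ArticularSurface:
    """Cached submesh of a bone's labeled articular faces, for distance
    queries during intrusion classification."""

    def __init__(self, mesh: SurfaceMesh):
        if mesh.face_labels is None:
            raise GeometryError(
                "mesh carries no articular face labels; generate or import a "
                "facet-label sidecar before intrusion classification"
            )
        self.articular_faces = np.flatnonzero(mesh.articular_mask)
        self._face_is_articular = mesh.articular_mask
        sub = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[self.articular_faces], process=False
        )
        self._submesh = sub

    def face_articular(self, face_index: int) -> bool:
        return bool(self._face_is_articular[face_index])

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance from points to the articular surface."""
        pts = np.atleast_2d(np.asarray(points, float))
        # brute force over the (small) articular submesh; avoids optional
        # spatial-index dependencies
        closest = trimesh.proximity.closest_point_naive(self._submesh, pts)[0]
        return np.linalg.norm(pts - closest, axis=1)


def classify_intrusion(
    exit_point: ExitPoint,
    articular: ArticularSurface,
    boundary_tol: float = INTRUSION_BOUNDARY_TOL,
) -> str:
    """Classify an exit point: intraarticular iff it lies on a labeled
    articular face or within ``boundary_tol`` of one (conservative tie-break
    toward intraarticular)."""
    if exit_point.missed:
        raise DegenerateInputError("cannot classify a missed exit point")
    if articular.face_articular(exit_point.face_index):
        label = "intraarticular"
    elif articular.articular_faces.size and float(
        articular.distance(exit_point.point)[0]
    ) <= boundary_tol:
        label = "intraarticular"
    else:
        label = "extraarticular"
    exit_point.intrusion = label
    return label


def exit_axis_distance(exit_point: ExitPoint, baseline_exit) -> float:
    """Euclidean distance between a deviated exit and the baseline (axis)
    exit on the same bone surface."""
    if exit_point.missed:
        return float("nan")
    return float(np.linalg.norm(exit_point.point - np.asarray(baseline_exit, float)))
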