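"""Synthetic two-bone specimens standing in for CT-derived hindfoot anatomy.

Each specimen is a pair of watertight superellipsoid "bone blobs" (talus and
calcaneus) with spherical articular facet patches carved in:

* facet sphere 1 - the posterior talar facet of the calcaneus: a convex dome
  on the calcaneus (radius ``r1`` about center ``c1``) and the mating concave
  patch on the talar underside (radius ``r1 + clearance`` about the same
  center);
* facet sphere 2 - the surrogate navicular facet: a convex dome on the talar
  head (radius ``r2`` about ``c2``).

The ground-truth subtalar rotation axis is the line joining ``c1`` and
``c2``.  Because both articulating surfaces of facet 1 are spheres centered
on that axis, rotation of the talus about it is a perfect ball-joint motion:
the inter-bone clearance at the facet is exactly preserved at every
inversion/eversion angle, which is what makes the configured range of motion
impingement-free by construction.

Landmarks for axis estimation are sampled area-uniformly on the labeled
facet faces, projected exactly onto the generating sphere (the idealised
"reference point placed on the articular surface"), then perturbed with
isotropic Gaussian noise of the requested standard deviation.

Everything is deterministic given the spec's seed.  Left-sided specimens are
generated as the mirror image (about the sagittal YZ plane) of their
right-sided twin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import InvalidSpecError
from .geometry import (
    LandmarkSet,
    RotationAxis,
    SurfaceMesh,
    estimate_subtalar_axis,
    estimate_talocrural_axis,
    make_vertical_axis,
)

# facet label codes
LABEL_POSTERIOR_FACET = 1
LABEL_NAVICULAR_FACET = 2


@dataclass(frozen=True)
class SpecimenSpec:
    """Parameters of one synthetic specimen.

    Defaults describe a plausible adult right hindfoot in the canonical frame
    (+X lateral, +Y anterior, +Z proximal, mm): a ~70 mm long calcaneus blob
    below, a ~45 mm talus blob above, a posterior facet of 13 mm radius of
    curvature, and a subtalar axis inclined anteromedially and proximally.
    """

    specimen_id: str = "S01"
    side: str = "right"
    # (center, radius) of the posterior-calcaneal-facet sphere
    facet_sphere_1: tuple = ((0.0, -18.0, -8.0), 13.0)
    # (center, radius) of the surrogate navicular (talar head) sphere
    facet_sphere_2: tuple = ((-3.0, 16.0, 9.0), 10.0)
    # multiplier applied to both bones' semi-axes
    bone_body_scale: tuple = (1.0, 1.0, 1.0)
    mesh_resolution: float = 2.0  # target edge length, mm
    landmark_count_per_facet: int = 8
    landmark_noise_sd: float = 0.0  # mm
    seed: int = 0
    # blob geometry (canonical right-foot frame, mm)
    talus_center: tuple = (0.0, 4.0, 9.0)
    talus_semiaxes: tuple = (16.0, 21.0, 11.0)
    calcaneus_center: tuple = (0.0, -8.0, -16.0)
    calcaneus_semiaxes: tuple = (22.0, 36.0, 13.0)
    superellipsoid_exponent: float = 2.4
    clearance: float = 2.0  # inter-bone gap along the facet normal, mm
    # facet cap half-angles / blend widths (degrees)
    cap1_half_angle: float = 35.0
    cap2_half_angle: float = 45.0
    cap_blend: float = 8.0
    # trochlear landmarks defining the talocrural axis (medial, lateral)
    trochlea_medial: tuple = (-16.0, -12.0, 14.0)
    trochlea_lateral: tuple = (16.0, -12.0, 14.0)

    def validate(self) -> None:
        c1, r1 = np.asarray(self.facet_sphere_1[0], float), float(self.facet_sphere_1[1])
        c2, r2 = np.asarray(self.facet_sphere_2[0], float), float(self.facet_sphere_2[1])
        if r1 <= 0 or r2 <= 0:
            raise InvalidSpecError("facet sphere radii must be positive")
        if self.mesh_resolution <= 0:
            raise InvalidSpecError("mesh_resolution must be positive")
        if self.landmark_count_per_facet < 4:
            raise InvalidSpecError("need >=4 landmarks per facet for sphere fitting")
        if self.landmark_noise_sd < 0:
            raise InvalidSpecError("landmark_noise_sd must be >= 0")
        if np.linalg.norm(c2 - c1) <= max(r1, r2) / 10.0:
            raise InvalidSpecError("facet sphere centers are (near-)coincident")
        if self.side not in ("left", "right"):
            raise InvalidSpecError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.clearance <= 0:
            raise InvalidSpecError("clearance must be positive")


@dataclass
class SyntheticSpecimen:
    """One generated specimen with its ground truth."""

    specimen_id: str
    side: str
    talus: SurfaceMesh
    calcaneus: SurfaceMesh
    landmarks: LandmarkSet
    true_subtalar_axis: RotationAxis
    true_talocrural_axis: RotationAxis
    true_vertical_axis: RotationAxis
    spec: SpecimenSpec | None = None
    meta: dict = field(default_factory=dict)

    def canonical(self) -> "SyntheticSpecimen":
        """Return the specimen in the canonical right-foot frame (mirror a
        left specimen; right specimens are returned unchanged)."""
        if self.side == "right":
            return self
        return SyntheticSpecimen(
            specimen_id=self.specimen_id,
            side="right",
            talus=self.talus.mirrored(),
            calcaneus=self.calcaneus.mirrored(),
            landmarks=self.landmarks.mirrored(),
            true_subtalar_axis=self.true_subtalar_axis.mirrored(),
            true_talocrural_axis=self.true_talocrural_axis.mirrored(),
            true_vertical_axis=self.true_vertical_axis.mirrored(),
            spec=self.spec,
            meta={**self.meta, "mirrored_from": self.side},
        )


# ---------------------------------------------------------------------------
# Blob + facet construction
# ---------------------------------------------------------------------------


def _icosphere_subdivisions(mean_semiaxis: float, resolution: float) -> int:
    # icosahedron edge on the unit sphere ~ 1.0515; each subdivision halves it
    s = math.ceil(math.log2(max(1.0515 * mean_semiaxis / resolution, 1.0)))
    return int(np.clip(s, 2, 6))


def _superellipsoid(center, semiaxes, exponent, resolution) -> SurfaceMesh:
    center = np.asarray(center, float)
    semiaxes = np.asarray(semiaxes, float)
    mean_ax = float(np.prod(semiaxes) ** (1.0 / 3.0))
    unit = trimesh.creation.icosphere(
        subdivisions=_icosphere_subdivisions(mean_ax, resolution), radius=1.0
    )
    d = np.asarray(unit.vertices)
    # radius of the superellipsoid surface along each unit direction
    r = np.sum(np.abs(d / semiaxes) ** exponent, axis=1) ** (-1.0 / exponent)
    verts = center + d * r[:, None]
    return SurfaceMesh(vertices=verts, faces=np.asarray(unit.faces))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _carve_facet(
    mesh: SurfaceMesh,
    center,
    radius: float,
    cap_direction,
    cap_half_angle_deg: float,
    blend_deg: float,
    label: int,
    radial_gate: float | None = None,
    radial_blend: float = 2.0,
) -> None:
    """Project in-cap vertices onto the sphere (center, radius), blending
    smoothly to the untouched blob at the cap rim, and label faces whose
    three vertices are fully projected.

    ``radial_gate``: for concave carves on the mating bone, only vertices
    within ``radius + radial_gate`` of the center participate (the far side
    of the bone may fall inside the cap cone but must not be pulled through
    the bone).
    """
    c = np.asarray(center, float)
    k = np.asarray(cap_direction, float)
    k = k / np.linalg.norm(k)
    rel = mesh.vertices - c
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arccos(np.clip(rel @ k / np.maximum(dist, 1e-12), -1, 1)))
    w = _smoothstep((cap_half_angle_deg - ang) / blend_deg)
    if radial_gate is not None:
        w = w * _smoothstep((radius + radial_gate - dist) / radial_blend)
    proj = c + rel * (radius / np.maximum(dist, 1e-12))[:, None]
    mesh.vertices = mesh.vertices + w[:, None] * (proj - mesh.vertices)
    full = w >= 1.0 - 1e-12
    face_full = full[mesh.faces].all(axis=1)
    if mesh.face_labels is None:
        mesh.face_labels = np.zeros(len(mesh.faces), dtype=np.int64)
    mesh.face_labels[face_full] = label
    mesh._trimesh = None  # invalidate cache


def _enforce_radial_clearance(
    talus: SurfaceMesh,
    calcaneus: SurfaceMesh,
    c1,
    clearance: float,
) -> None:
    """Push talar vertices radially (from the facet sphere center ``c1``) so
    they sit at least ``clearance`` above the carved calcaneal surface.

    Both bones are star-shaped as seen from ``c1`` (convex blobs with radial
    facet projections), so the radial distance from ``c1`` is an exact
    inside/outside criterion against the triangulated calcaneal surface.
    The labeled talar facet already sits at exactly ``sphere radius +
    clearance`` above the facet dome and is untouched.
    """
    from scipy.spatial import cKDTree

    from .geometry import _ray_triangle_distances

    c1 = np.asarray(c1, float)
    rel = talus.vertices - c1
    dist = np.linalg.norm(rel, axis=1)
    dirs = rel / dist[:, None]
    # only vertices near the calcaneal surface can violate the clearance
    edge = float(np.median(calcaneus.as_trimesh().edges_unique_length))
    near, _ = cKDTree(calcaneus.vertices).query(talus.vertices)
    cand = np.flatnonzero(near < clearance + 2.0 * edge)
    if cand.size == 0:
        return
    tri = calcaneus.vertices[calcaneus.faces]
    moved = False
    for i in cand:
        t, mask = _ray_triangle_distances(c1, dirs[i], tri)
        if not mask.any():
            continue
        calc_r = float(t[mask].max())  # outermost crossing = surface radius
        floor = calc_r + clearance
        if dist[i] < floor - 1e-9:
            talus.vertices[i] = c1 + dirs[i] * floor
            moved = True
    if moved:
        talus._trimesh = None


def _enforce_motion_clearance(
    talus: SurfaceMesh,
    calcaneus: SurfaceMesh,
    c1,
    axes_and_angles,
    guard: float = 0.3,
    max_iter: int = 4,
) -> None:
    """Push talar vertices radially from ``c1`` until no protocol position
    leaves them inside (or within ``guard`` of) the calcaneal surface.

    Radial clearance at a vertex's own direction is not rotation-invariant:
    a vertex can rotate into a direction where the calcaneal surface sits
    higher (the facet dome next to a low blob region).  Rotation about the
    subtalar axis (through ``c1``) preserves the radius from ``c1``, so an
    outward radial push fixes all its positions at once; the vertical-axis
    positions converge within a few iterations.  Vertices of labeled talar
    faces are never moved - the concave facet's clearance over the dome is
    exact by construction.
    """
    from scipy.spatial import cKDTree

    from .geometry import _ray_triangle_distances, rotation_matrix

    c1 = np.asarray(c1, float)
    protected = np.zeros(len(talus.vertices), dtype=bool)
    if talus.face_labels is not None:
        protected[np.unique(talus.faces[talus.face_labels > 0])] = True
    edge = float(np.median(calcaneus.as_trimesh().edges_unique_length))
    tree = cKDTree(calcaneus.vertices)
    tri = calcaneus.vertices[calcaneus.faces]
    rots = [
        (np.asarray(axis.point, float), rotation_matrix(axis.direction, ang))
        for axis, ang in axes_and_angles
    ]
    for _ in range(max_iter):
        near, _ = tree.query(talus.vertices)
        cand = np.flatnonzero((near < 3.0 * edge + guard) & ~protected)
        if cand.size == 0:
            return
        v = talus.vertices[cand]
        rel0 = v - c1
        r0 = np.linalg.norm(rel0, axis=1)
        dirs0 = rel0 / r0[:, None]
        push = np.zeros(cand.size)
        for apoint, rot in rots:
            vr = (v - apoint) @ rot.T + apoint
            rel = vr - c1
            rr = np.linalg.norm(rel, axis=1)
            dd = rel / rr[:, None]
            for j in range(cand.size):
                t, mask = _ray_triangle_distances(c1, dd[j], tri)
                if mask.any():
                    deficit = float(t[mask].max()) + guard - rr[j]
                    if deficit > 1e-9:
                        push[j] = max(push[j], deficit)
        moved = push > 0.0
        if not moved.any():
            return
        talus.vertices[cand[moved]] = (
            c1 + dirs0[moved] * (r0[moved] + push[moved])[:, None]
        )
        talus._trimesh = None


def _sample_on_labeled_faces(
    mesh: SurfaceMesh, label: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Area-uniform sample of points on faces carrying ``label``."""
    idx = np.flatnonzero(mesh.face_labels == label)
    if idx.size == 0:
        raise InvalidSpecError(f"no faces labeled {label}; facet cap too small")
    tri = mesh.vertices[mesh.faces[idx]]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    pick = rng.choice(idx.size, size=count, p=area / area.sum())
    # uniform barycentric coordinates
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    bary = np.stack([1 - r1, r1 * (1 - r2), r1 * r2], axis=1)
    return np.einsum("nk,nkd->nd", bary, tri[pick])


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def generate_specimen(spec: SpecimenSpec) -> SyntheticSpecimen:
    """Generate one synthetic specimen from its spec (deterministic in the
    spec's seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scale = np.asarray(spec.bone_body_scale, float)

    c1 = np.asarray(spec.facet_sphere_1[0], float)
    r1 = float(spec.facet_sphere_1[1])
    c2 = np.asarray(spec.facet_sphere_2[0], float)
    r2 = float(spec.facet_sphere_2[1])
    t_center = np.asarray(spec.talus_center, float)

    calcaneus = _superellipsoid(
        spec.calcaneus_center,
        np.asarray(spec.calcaneus_semiaxes) * scale,
        spec.superellipsoid_exponent,
        spec.mesh_resolution,
    )
    calcaneus.name = "calcaneus"
    talus = _superellipsoid(
        spec.talus_center,
        np.asarray(spec.talus_semiaxes) * scale,
        spec.superellipsoid_exponent,
        spec.mesh_resolution,
    )
    talus.name = "talus"

    # convex posterior-facet dome on the calcaneus
    k1 = t_center - c1
    _carve_facet(
        calcaneus, c1, r1, k1, spec.cap1_half_angle, spec.cap_blend, LABEL_POSTERIOR_FACET
    )
    # mating concave patch on the talar underside, offset by the clearance
    _carve_facet(
        talus,
        c1,
        r1 + spec.clearance,
        k1,
        spec.cap1_half_angle,
        spec.cap_blend,
        LABEL_POSTERIOR_FACET,
        radial_gate=6.0,
    )
    # convex navicular dome on the talar head
    k2 = c2 - t_center
    _carve_facet(
        talus, c2, r2, k2, spec.cap2_half_angle, spec.cap_blend, LABEL_NAVICULAR_FACET
    )
    # guarantee the inter-bone clearance radially from the facet center (the
    # carve blend rims of the two bones carry no ordering guarantee) ...
    _enforce_radial_clearance(talus, calcaneus, c1, spec.clearance)
    # ... and across the simulated range of motion (below, once the motion
    # axes are in hand: rim vertices can rotate over the facet dome)

    # landmarks: exact on-sphere placement + isotropic noise
    lm_calc = _sample_on_labeled_faces(
        calcaneus, LABEL_POSTERIOR_FACET, spec.landmark_count_per_facet, rng
    )
    lm_calc = c1 + (lm_calc - c1) * (r1 / np.linalg.norm(lm_calc - c1, axis=1))[:, None]
    lm_nav = _sample_on_labeled_faces(
        talus, LABEL_NAVICULAR_FACET, spec.landmark_count_per_facet, rng
    )
    lm_nav = c2 + (lm_nav - c2) * (r2 / np.linalg.norm(lm_nav - c2, axis=1))[:, None]
    if spec.landmark_noise_sd > 0:
        lm_calc = lm_calc + rng.normal(0.0, spec.landmark_noise_sd, lm_calc.shape)
        lm_nav = lm_nav + rng.normal(0.0, spec.landmark_noise_sd, lm_nav.shape)

    landmarks = LandmarkSet(
        groups={LandmarkSet.CALCANEAL: lm_calc, LandmarkSet.NAVICULAR: lm_nav},
        points={
            "trochlea_medial": np.asarray(spec.trochlea_medial, float),
            "trochlea_lateral": np.asarray(spec.trochlea_lateral, float),
        },
    )

    subtalar = RotationAxis(
        point=c1,
        direction=(c2 - c1) / np.linalg.norm(c2 - c1),
        convention="inversion_positive",
    )
    talocrural = estimate_talocrural_axis(
        np.asarray(spec.trochlea_medial, float), np.asarray(spec.trochlea_lateral, float)
    )
    vertical = make_vertical_axis(talocrural)

    # the simulated motion runs about the landmark-estimated subtalar axis,
    # which deviates from the ground truth under landmark noise: enforce the
    # clearance at the extreme positions of both the true and the estimated
    # axes (the estimate here is exactly what the pipeline will recompute
    # from these same landmarks)
    extremes = [(subtalar, -9.0), (subtalar, 9.0), (vertical, -9.0), (vertical, 9.0)]
    if spec.landmark_noise_sd > 0:
        est_subtalar = estimate_subtalar_axis(landmarks)
        extremes += [(est_subtalar, -9.0), (est_subtalar, 9.0)]
    _enforce_motion_clearance(talus, calcaneus, c1, extremes)

    out = SyntheticSpecimen(
        specimen_id=spec.specimen_id,
        side="right",
        talus=talus,
        calcaneus=calcaneus,
        landmarks=landmarks,
        true_subtalar_axis=subtalar,
        true_talocrural_axis=talocrural,
        true_vertical_axis=vertical,
        spec=spec,
        meta={"clearance": spec.clearance},
    )
    if spec.side == "left":
        out = _mirror_specimen(out)
    return out


def _mirror_specimen(sp: SyntheticSpecimen) -> SyntheticSpecimen:
    return SyntheticSpecimen(
        specimen_id=sp.specimen_id,
        side="left",
        talus=sp.talus.mirrored(),
        calcaneus=sp.calcaneus.mirrored(),
        landmarks=sp.landmarks.mirrored(),
        true_subtalar_axis=sp.true_subtalar_axis.mirrored(),
        true_talocrural_axis=sp.true_talocrural_axis.mirrored(),
        true_vertical_axis=sp.true_vertical_axis.mirrored(),
        spec=sp.spec,
        meta=sp.meta,
    )


def generate_cohort(specs: list[SpecimenSpec]) -> list[SyntheticSpecimen]:
    """Generate one specimen per spec; specimen ids must be unique."""
    if not specs:
        raise InvalidSpecError("cohort needs at least one specimen spec")
    ids = [s.specimen_id for s in specs]
    if len(set(ids)) != len(ids):
        raise InvalidSpecError(f"duplicate specimen ids in cohort: {ids}")
    return [generate_specimen(s) for s in specs]


def default_cohort_specs(
    n: int = 10,
    seed: int = 0,
    landmark_noise_sd: float = 0.1,
    mesh_resolution: float = 2.0,
) -> list[SpecimenSpec]:
    """Cohort specs emulating 10 healthy ankles: the default anatomy jittered
    per specimen (facet radii +-8%, sphere centers +-1.5 mm, bone scale
    +-6%), sides alternating right/left for an equal distribution.

    The jitter magnitudes are desk-chosen to give visibly distinct but
    structurally identical specimens; no shape statistics of a real cohort
    are available to calibrate against.
    """
    if n < 1:
        raise InvalidSpecError("cohort size must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n) % (2**31)
    rng = np.random.default_rng(seeds[0])
    base = SpecimenSpec()
    specs = []
    for i in range(n):
        c1 = np.asarray(base.facet_sphere_1[0]) + rng.uniform(-1.5, 1.5, 3)
        r1 = base.facet_sphere_1[1] * rng.uniform(0.92, 1.08)
        c2 = np.asarray(base.facet_sphere_2[0]) + rng.uniform(-1.5, 1.5, 3)
        r2 = base.facet_sphere_2[1] * rng.uniform(0.92, 1.08)
        scale = rng.uniform(0.94, 1.06, 3)
        specs.append(
            replace(
                base,
                specimen_id=f"S{i + 1:02d}",
                side="right" if i % 2 == 0 else "left",
                facet_sphere_1=(tuple(c1), float(r1)),
                facet_sphere_2=(tuple(c2), float(r2)),
                bone_body_scale=tuple(scale),
                landmark_noise_sd=landmark_noise_sd,
                mesh_resolution=mesh_resolution,
                seed=int(seeds[n + i]),
            )
        )
    return specs
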