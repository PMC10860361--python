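# Methods

## Overview

`subtalarsim` evaluates candidate bone-tunnel placements for a ligament
reconstruction spanning the subtalar space. The pipeline has five stages:

1. **anatomy** — either imported talus/calcaneus surface meshes with a
   landmark/label sidecar, or synthetic specimens (below);
2. **axes** — least-squares sphere fits to two articular landmark groups
   give the subtalar rotation axis; two trochlear landmarks give the
   talocrural axis, whose midpoint anchors a vertical subluxation axis;
3. **tunnels** — 33 candidate exit points per bone by angular deviation of
   the axis-aligned baseline tunnel, each classified extra-/intraarticular;
4. **simulation** — ligament length variation Δ(α) for all 1089 exit-point
   pairings across 7 inversion/eversion and 7 internal/external rotation
   positions;
5. **selection** — cohort aggregation, intrusion filtering and lexicographic
   ranking.

All computations are in the canonical right-foot frame (+X lateral,
+Y anterior, +Z proximal, millimetres); left-sided specimens are mirrored
about the sagittal plane at generation or import.

## Kinematic model and assumptions

Subtalar motion is modelled as rotation about a single fixed (helical) axis
determined by bone morphology: the line through the centers of spheres
fitted to the posterior talar facet of the calcaneus and to the navicular
facet of the talar head. This is a deliberate simplification — in vivo
subtalar motion combines sliding, rolling and spinning — but it makes the
exhaustive 1089-combination sweep tractable and deterministic. Peritalar
subluxation is modelled as rotation about a vertical (+Z) axis placed at the
talocrural-axis midpoint; the true subluxation axis of the deformity is not
known quantitatively, and the vertical axis is chosen for reproducibility.

The talus moves, the calcaneus stays fixed; only relative motion affects
ligament length. Sign conventions (right-hand rule): positive subtalar
angle = inversion; positive vertical-axis angle = internal talar rotation.
The ligament is the straight exit-to-exit segment; curvature around bone
contours is not modelled, which underestimates strain for wrapping paths.
No forces, graft stiffness or tissue properties enter anywhere — the
analysis is strictly kinematic.

## Synthetic anatomy

Each synthetic specimen is a pair of watertight superellipsoid bodies
(exponent 2.4) with spherical facet patches blended in by radial projection:

* a convex posterior-facet dome on the calcaneus (sphere center `c1`,
  radius `r1`, default 13 mm);
* the mating concave patch on the talar underside at radius
  `r1 + clearance` about the same center (clearance default 2 mm along the
  facet normal);
* a convex navicular dome on the talar head (center `c2`, radius `r2`,
  default 10 mm).

The ground-truth subtalar axis joins `c1` and `c2`. Because both
articulating surfaces of the posterior facet are spheres centered on that
axis, inversion/eversion is an exact ball-joint motion and preserves the
2 mm facet clearance at every angle; this is what makes the default ±9°
range of motion impingement-free by construction. Two enforcement passes extend that
guarantee beyond the facet itself: a static pass clamps talar vertices
radially from `c1` against the triangulated calcaneal surface (both bodies
are star-shaped from `c1`, so the radial gap is an exact inside/outside
criterion), and a motion-aware pass iteratively pushes rim vertices outward
until every extreme protocol position is clear — needed because a vertex's
radial clearance at its own direction is not rotation-invariant (rim
vertices can rotate over the facet dome). Labeled facet vertices are never
moved by either pass.

Faces whose three vertices are fully projected onto a facet sphere are
labeled articular; their vertices lie on the generating sphere to machine
precision. Landmarks (default 8 per facet, chosen within the 4–8+ range the
sphere fit accepts) are sampled area-uniformly on labeled faces, projected
exactly onto the generating sphere — the idealised "reference point placed
on the articular surface" — and then perturbed with isotropic Gaussian noise
(default SD 0.1 mm, emulating manual placement error).

The default cohort jitters facet radii (±8%), sphere centers (±1.5 mm) and
bone scale (±6%) per specimen and alternates right/left sides. The jitter
magnitudes are a design choice: no shape statistics of a real cohort are
available to calibrate against, so the synthetic cohort demonstrates the
mechanism and the pipeline's invariants, not patient anatomy. In
particular, absolute outputs (mean neutral length ≈ 5.6 mm here, exit-to-axis
distances, Δ magnitudes) are properties of the synthetic shape parameters.
What the passing tests show is that the *method* is correct (exact
recoveries, invariants, oracle agreement); they cannot show that real
anatomy yields any particular millimetre value.

## Numerical choices

* **Sphere fit**: algebraic (Pratt-style) linear least squares initialises a
  geometric Levenberg–Marquardt refinement of Σ(|p−c|−r)²; tolerance
  1e-10 mm, ≤100 iterations; exact on points that lie exactly on a sphere.
  <4 points or a coplanar set raises a degenerate-input error.
* **Ray–mesh intersection**: vectorised Möller–Trumbore over all triangles;
  hits within 1e-9 mm of the origin are discarded (surface-anchored rays),
  duplicate hits on shared edges merged at 1e-7 mm.
* **Entry/exit anchors**: all subtalar-axis/mesh intersections are ordered
  along the axis; the two hits bounding the inter-bone gap are the baseline
  exits, the outermost hit per bone its entry.
* **Deviated exits**: a tilted ray's exit is the last surface hit on the
  bone's own side of the gap midplane; if every hit lies beyond the midplane
  (strong distal deviations emerging on the anterior calcaneal process), the
  first hit — where the ray leaves the bone interior — is used. A ray with
  no hit is flagged missed and its combinations are skipped, not fatal.
* **Intrusion**: an exit is intraarticular if its face is labeled or if it
  lies within 0.1 mm of a labeled face (conservative tie-break toward
  intraarticular, configurable).
* **Impingement**: a validation report, not a motion limiter. Talus
  vertices near the calcaneus (KDTree prefilter) are tested for containment
  by ray-crossing parity against the watertight calcaneal mesh; penetrations
  below 0.05 mm (sub-resolution) are not reported. The default synthetic
  cohort reports no contact at any protocol position, with either the
  ground-truth or the landmark-estimated axes; with much larger landmark
  noise the estimated axes can drift enough for marginal contacts to appear,
  and the report will say so.
* **Δ(0) = 0 exactly**: the neutral length is subtracted symbolically, never
  recomputed through the rotation path; a zero-angle rotation returns its
  input bit-for-bit.
* **Aggregation**: per-position mean/SD across specimens with t-based 95%
  CIs on the specimen dimension; a single-specimen cohort reports means only
  and flags SD/CI unavailable. Extraarticular frequency is evaluated per
  exit ray (fraction of specimens), and a combination's eligibility uses its
  talar and calcaneal ray frequencies.
* **Ranking**: lexicographic — descending mean Δ at the objective position
  (maximal internal rotation by default), ascending inversion/eversion
  excursion (max |mean Δ| over that motion), then a deterministic
  (talar plane, θ, calcaneal plane, θ) tie-break. The "lowest strain in
  inversion and eversion" requirement is not uniquely defined; the
  lexicographic form was chosen because it is deterministic, total, and
  reproducible by exhaustive enumeration.
* **Percent variation** uses each specimen's own neutral length L(0) as the
  denominator.
* **CSV output** uses 6 significant digits, exceeding the 0.01 mm reporting
  granularity of the quantities involved; identical config + seed give
  byte-identical outputs.

## Deviation-plane convention

Within each deviation plane, positive θ points toward the second-named
pole: `proximal_distal` → distal, `medial_lateral` → lateral,
`lateroproximal_mediodistal` → mediodistal, `medioproximal_laterodistal` →
laterodistal ("laterodistal 6°" ≡ plane `medioproximal_laterodistal`,
θ = +6). The diagonal planes bisect the cardinal planes at 45°. The frame
at each entry point is built from the subtalar axis direction (signed toward
the other bone) and the talocrural direction orthogonalised against it;
"8 reference points" per facet and the two-landmark talocrural construction
are package conventions where the underlying anatomy admits alternatives.

## Problem sizes

The default study runs 10 specimens × 1089 combinations × 14 positions
(152,460 length evaluations, vectorised) plus 140 impingement checks; a full
run — cohort generation with clearance enforcement, simulation and
impingement validation — completes in about a minute on one CPU. The test
suite uses a
three-specimen cohort for pipeline-level checks and the full ten-specimen
cohort for the determinism check.

## Known limitations

* The synthetic bones are smooth convex-ish bodies; real tali and calcanei
  have processes, non-spherical facets and cartilage, so intrusion
  percentages and absolute lengths are not transferable.
* Cartilage is absent; impingement is bone-on-bone only and therefore
  underestimated relative to reality.
* The vertical subluxation axis is a convention, not a measured deformity
  axis; tunnel-bore diameter and drill-path feasibility are out of scope.
* The sphere-fit center error under landmark noise is anisotropic (largest
  along the facet-cap normal, since landmarks sample a shallow cap); the
  pipeline reports the resulting axis-error distribution rather than
  asserting a bound.
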