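# subtalarsim

Kinematic simulation of subtalar (talocalcaneal) ligament reconstruction.

## The problem

In progressive collapsing foot deformity (PCFD, adult acquired flatfoot) the
talus rotates internally and plantarly relative to the calcaneus, producing a
painful peritalar subluxation. A ligament reconstruction spanning the
subtalar space — a surrogate interosseous talocalcaneal ligament (ITCL)
running through the tarsal canal — could resist that internal rotation
directly, provided its bone tunnels are placed so that the graft

* **lengthens** under internal talar rotation (it resists the subluxation),
* stays **near-isometric** during physiological inversion/eversion (it does
  not block normal hindfoot motion), and
* exits **extraarticularly** on both bones (it does not violate the
  articular facets).

`subtalarsim` implements that tunnel-placement analysis as a reproducible
pipeline for pairs of talus/calcaneus surface meshes, together with a
synthetic-anatomy generator that emulates a cohort of CT-derived hindfeet.

## The model

The subtalar joint is idealised as a single rigid rotation axis: the line
joining the centers of two least-squares spheres fitted to landmarks on the
posterior talar facet of the calcaneus and on the (surrogate) navicular
facet of the talar head. Two motions are simulated, with the calcaneus fixed:

* inversion/eversion: rotation of the talus about the subtalar axis,
  α = −9° … +9° in 3° steps (7 positions);
* internal/external peritalar rotation: rotation about a vertical axis
  through the talocrural-axis midpoint, same protocol.

The baseline tunnel on each bone runs along the subtalar axis; candidate
tunnels tilt that direction about the entry point by θ ∈ {±2°, ±4°, ±6°, ±8°}
in four deviation planes oriented by the talocrural axis
(proximal–distal, medial–lateral, lateroproximal–mediodistal,
medioproximal–laterodistal): 4×8 + 1 = **33 exit points per bone**, hence
**33 × 33 = 1089 candidate ligaments**. For each candidate the ligament is
the straight segment between exit points and its length variation at a
position α is

    Δ(α) = L(α) − L(0)        [mm, also reported as % of L(0)]

Per-combination Δ profiles are aggregated across the cohort (mean, SD,
t-based 95% CI), exit points are classified extra-/intraarticular against
labeled facet faces, and combinations with a talar exit extraarticular in
≥90% and a calcaneal exit in ≥70% of specimens are ranked by largest mean
Δ at maximal internal rotation, breaking ties toward the smallest
inversion/eversion excursion.

## Worked example

```python
from subtalarsim import SubtalarLigamentModel

model = SubtalarLigamentModel.from_synthetic_cohort(n_specimens=10, seed=0)
res = model.fit()
print(res.summary())
```

prints (abbreviated):

```
Subtalar ligament reconstruction - kinematic simulation
============================================================
specimens:                 10
tunnel combinations:       1089
positions (inv/eversion):  7
positions (int/external):  7
mean neutral length L0:    5.63 mm

selection criteria: talar extraarticular >= 90%, calcaneal >= 70%
combinations passing:      28

top 4 combinations (Δ at maximal internal rotation; inversion/eversion excursion):
   1. talar   mediodistal 8 | calcaneal        distal 8 | Δ_IR +1.576 mm (+31.4% of L0) | iso 0.5917 mm
   2. talar   mediodistal 8 | calcaneal  laterodistal 8 | Δ_IR +1.505 mm (+17.5% of L0) | iso 0.4455 mm
   ...
```

Each line is one candidate reconstruction: which talar and calcaneal tunnel
orientation it uses, how much the ligament lengthens at 9° internal talar
rotation (absolute and relative to its neutral length), and its largest mean
|Δ| across all inversion/eversion positions (smaller = closer to isometric).
Distal/laterodistal calcaneal tunnels resist internal rotation;
`res.opposite_selection()` repeats the selection for the external-rotation
objective under relaxed intrusion thresholds, which favours the opposite
(mediodistal/medioproximal) calcaneal orientations.

The same run is available from the shell:

```bash
subtalar-sim run-all --n-specimens 10 --seed 0 --output-dir results/
```

which writes the exit-point table, the long-format strain table, the cohort
summary, the ranked selection and a machine-readable run manifest.
Subcommands `synth`, `axes`, `tunnels`, `simulate` and `select` expose the
individual stages; identical config + seed reproduce byte-identical outputs.

## Limitations

The synthetic cohort reproduces the *mechanism* (two bones articulating
through spherical facets with a known rotation axis), not real hindfoot
anatomy; absolute millimetre values depend on the synthetic shape parameters
and are not comparable to patient-derived measurements. The analysis is
strictly kinematic: no graft tension, stiffness, or wrap-around curvature is
modelled. See `docs/methods.md` for the full method description and design
choices.
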