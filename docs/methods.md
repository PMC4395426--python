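# Methods

## Model

`imcsim` is a center-based (off-lattice) model of collective cell
migration. Every cell is an identical rigid disc (2D) or sphere (3D) of
diameter D = 7 µm; a small cell (border, polar, epithelial) is one such
unit, while each large nurse cell is an adhesive aggregate of many units
sharing a group id. Dynamics are overdamped: inertia is neglected and
each cell's velocity equals the net force on it, with the damping
coefficient absorbed into composite force coefficients. All lengths are
expressed in units of D and times in hours, so one Euler step of 0.005
time units corresponds to 18 seconds.

For cell *i* at position **U**ᵢ the equation of motion is

    dUᵢ/dt = Σⱼ (Fᵃᵢⱼ + Fʳᵢⱼ) + Σ eligible pairs Fᵐᵢⱼ + Fˢᵢ

with four force classes, writing r = ‖Uⱼ − Uᵢ‖ and d̂ the unit vector
from *i* to *j*:

- **Adhesion** Fᵃ = Cᵃᵢⱼ ρᵉ H(ρᵉ) d̂ — a linear spring in the extended
  overlap ρᵉ = (1 + ε) − r, active while the cells are within the
  adhesive reach ε of contact. The coefficient Cᵃᵢⱼ depends on the pair
  class (see the table below).
- **Repulsion** Fʳ = −Cʳ (ρ⁰)³ H(ρ⁰) d̂ — cubic in the contact overlap
  ρ⁰ = 1 − r; zero unless the cells physically overlap, and stiffening
  as they are squeezed.
- **Migration** Fᵐ = Cᵐ σᵢⱼ Proj⊥d̂ ∇f — border cells push off adjacent
  non-motile cells in the direction of the chemoattractant gradient ∇f
  projected perpendicular to the contact axis (the component along the
  contact line does work against the partner, not past it). σ = +1 for
  the migratory member of the pair, −1 for its passive partner, 0 when
  both or neither are migratory. The gradient defaults to a constant
  unit vector along the anterior→posterior axis; any magnitude is
  absorbed into Cᵐ.
- **Stochastic** Fˢ = Cˢ ζ — independent zero-mean, unit-SD Gaussian
  components per cell per step, scaled by Cˢ, standing in for
  protrusive noise.

All deterministic pair forces are antisymmetric under i↔j, so the free
system conserves its centroid exactly (checked to 1e-10 D over 1000
steps in the tests).

## Parameters

Composite, non-dimensional defaults:

| parameter | value | meaning |
|---|---|---|
| Cᵃ border–border | 1.872 | cluster cohesion |
| Cᵃ polar–polar | 1.872 | polar pair cohesion |
| Cᵃ polar–border | 7.02 | strong core adhesion holding the cluster around the polar cells |
| Cᵃ epithelial–epithelial | 7.02e-4 | boundary shell (fixed shortly after start, so dynamically inert) |
| Cᵃ same nurse cell | 7.02e-4 | aggregate cohesion |
| Cᵃ basal (all other pairs) | 7.02e-4 | background stickiness |
| Cʳ | 15.6 | contact repulsion, identical for all pairs |
| Cᵐ | 1.56 | migratory push per active pair |
| Cˢ | 5 | stochastic force SD |
| ε | 0.45 | adhesive reach, units of D; must satisfy 0 < ε < 1/2 |
| dt | 0.005 | Euler step (18 s) |
| neighbor cutoff | 2 D | pair list radius, refreshed every 0.2 time units |
| epithelium fix time | 0.1 | epithelial cells frozen after 6 simulated minutes |

The basal adhesion level is set to the epithelial/nurse composite value
(multiplier one). ε = 0.45 puts the isolated polar–polar equilibrium
separation near 0.52 D, the root of 1.872(1.45 − r) = 15.6(1 − r)³.

An intrinsic property of these coefficients worth knowing: the
polar–border pair force is net-attractive down to r ≈ 0.17 D, so inside
a full cluster the border cells compress the polar pair well below its
isolated equilibrium (typical in-cluster polar separation 0.25–0.35 D).
This compaction shapes several emergent results discussed under
Limitations.

## Numerical scheme

Forward Euler with a fixed step. The stochastic force enters the update
as dt·Cˢ·ζ per step — plain forcing, as a force term in the equation of
motion, not √dt (Euler–Maruyama) scaling — so the effective diffusion
depends on the step size; dt is therefore part of the model definition
and is held at 0.005 everywhere. Without noise the scheme is first
order (endpoint-error ratio ≈ 2 under dt halving, asserted in the
tests). Pair interactions use a KD-tree neighbor list at a 2-diameter
cutoff refreshed every 0.2 simulated time units; forces vanish beyond
1 + ε = 1.45 D, and at default parameters no cell travels the remaining
margin within a refresh window (verified against all-pairs dynamics to
1e-6 D). One Gaussian vector is drawn per cell per step in cell-id
order from a single seeded generator, making trajectories bitwise
reproducible. Coincident centres (closer than 1e-6 D) are rejected at
initialization and detected during stepping; non-finite positions abort
the run naming the cell and step.

Migratory pair eligibility: the quoted sign rule alone would let border
cells push off the polar cells they carry. By default the migratory
interaction is restricted to border cells against substrate (nurse,
epithelial, oocyte-surface) cells — the interaction the model text
describes — while a configuration switch
(`restrict_migratory_to_substrate: false`) restores the pure sign rule.
The migratory force is gated on pair interaction (extended overlap
positive); `migratory_gate: contact` restricts it to physical contact
instead.

## Domain construction

The egg chamber is a box with the anterior→posterior axis along x:
default length 22 D (≈ 154 µm, matching the ~150 µm migration path) and
a 10 × 10 D cross-section. Epithelial cells occupy a unit-spaced lattice
on every face except the posterior one, which carries the fixed
oocyte-surface layer (the migration target). Fifteen nurse cells are
spheres of radius 2.5 D (≈ 35 µm, the ~5× size ratio to epithelial
cells) packed with unit cells on an FCC lattice at 0.95 D spacing,
arranged in five axial stations of three around the axis, each station's
ring rotated 60° from its neighbors. Stations span the full interior
(sphere centres from r + 0.5 to length − r − 0.5) so nurse material
reaches both the anterior region and the oocyte face. The migratory
cluster — two polar cells side by side at the core, border cells on a
shell of radius 1.2 D around them — seats on the axis 2 D inside the
anterior face. Cells are placed in the order cluster, epithelium,
oocyte, nurse; any nurse member closer than 0.8 D to an existing cell is
dropped, which carves the nurse cells around the cluster and the walls.
Construction is fully deterministic.

Because three 2.5 D spheres per station cannot avoid overlapping inside
a 10 D cross-section, the carving leaves interstitial voids between
nurse cells (the interior is ~46% occupied). These voids are the "gaps
between nurse cells" of the biological system: the cluster squeezes
through them, and tumbling concentrates near them. An alternative
builder (`nurse_fill: tiled`) packs the entire interior with one lattice
and partitions it among the nurse centres; in that denser medium the
migratory forces on individual border cells exceed what cluster cohesion
can hold and the cluster shears apart, so the sphere fill is the
default.

2D cross-section presets mirror the 3D construction with six nurse
discs in three stations of two and a triangular lattice.

## Study conditions and measurements

The reference study runs the default 3D chamber with 6 border + 2 polar
cells and replicates the sweep at 4 and 8 border cells, all other
parameters identical. Arrival is the earliest recorded time any cluster
cell centre comes within 1 D of an oocyte-surface cell centre
(configurable; a centroid-crossing alternative is available via the
contact distance). Rotation is tracked along the anterior→posterior
axis only: the relative lead ℓ(t) is the axial coordinate difference of
the two polar cells (µm), a *clear lead switch* is a sign change of ℓ
confirmed by |ℓ| exceeding 0.1 D before the next sign change, and the
maximal rotation angle is estimated as

    θ = arcsin(L₊/d̄) + arcsin(L₋/d̄)

with L₊, L₋ the maximal leads either way and d̄ the time-mean polar
separation (arguments clipped to 1 with a warning; θ = 0 if the lead
never changes sign). With leads of ±1.4 µm and d̄ = 3.6 µm this
estimator gives ≈ 45.8°.

Problem sizes used by `scripts/acceptance.py`: ten seeded full
migrations at 6 border cells (arrival mean/SD and, from their first two
simulated hours, switch and rotation statistics), three seeds at 8
border cells, one seed at 4 border cells; ~2,300 cells per run.

## Limitations

- The true nurse-cell IMC count, chamber cross-section and aggregate
  arrangement behind the reference results are not recoverable; the
  domain here is a reconstruction, and arrival times are sensitive to
  the interior fill (reconstruction variants span roughly 3–9 h for the
  6-cell cluster). The measured mean at defaults is ~5 h.
- In-cluster compaction (see Parameters) keeps the polar pair much
  closer than the isolated equilibrium; the arcsine rotation estimator
  then saturates (leads comparable to the separation), and small
  clusters remain fully enveloped, so the 4-cell cluster is not slowed
  by polar-cell drag in this reconstruction — it arrives about as fast
  as larger ones, unlike the reference behaviour.
- Arrival-time variance across seeds is dominated by stall episodes in
  interstitial voids (minutes-to-hours), far larger than the sub-minute
  reference variability.
- The box is a rectangular prism, not a capped ellipsoid; cells are
  rigid, with no division, death or type conversion; the gradient is
  constant and does not saturate.
- The synthetic domain generator emulates geometry and type
  composition, not image-derived anatomy, so passing tests demonstrate
  the force model's behaviour in this reconstructed environment, not
  agreement with any particular biological egg chamber.
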