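# Model and methods

`semcell` simulates single cells and small tissues as ensembles of
coarse-grained particles (a subcellular-element model) advanced by
overdamped Brownian dynamics, with discrete biological events (migration
turnover, growth, division) layered on top and a mechanics layer that
computes per-particle stress and strain.

## The particle model

One cell of radius `R_cell` is represented by `Np` cytoplasmic particles
and optionally one rigid nuclear particle.  Cytoplasmic pairs interact via
the Morse-like potential

    V(d) = u0 exp(2ρ(1 − d²/d_eq²)) − α u0 exp(ρ(1 − d²/d_eq²)),

truncated (not shifted) at `r_cut = 2.5 d_eq`; for `α = 2` the minimum sits
exactly at `d_eq` with depth `−u0`.  The interaction constants are derived
from cell-level rheology so that cells of any particle count have the same
mechanics:

    d_eq = 2 R_cell (p_d / Np)^(1/3)
    κ    = κ0 Np^(−1/3) (1 − λ Np^(−1/3))
    u0   = κ d_eq² / (8 ρ²)
    η    = η0 · Np^(drag_exponent)

Defaults (10 µm cell): `p_d = 0.74`, `ρ = α = 2`, `κ0 = 5×10⁻³ N/m`,
`η0 = 5×10⁻³ N·s/m`, `λ = 0.75`.  At `Np = 1000` this gives
`d_eq = 1.81 µm`, `κ = 4.6×10⁻⁴ N/m`, `u0 = 4.7×10⁻¹⁷ J`.

**Drag scaling.**  The per-particle drag is `η0/Np` (`drag_exponent = −1`,
configurable to −1/3 or +1).  This makes the total translational drag of a
cell independent of its particle count and gives a pair relaxation time
`η/κ ≈ 0.011 s` at the reference count, so cell-scale creep equilibrates on
the seconds scale.  The nucleus drag is `m_nuc_factor` (50) times the
cytoplasmic drag — the behaviour of a Langevin thermostat with a fixed damp
time and mass-proportional friction.  The no-bias nuclear drift during
migration is structural (set by particle turnover, not by how fast the
nucleus can follow), so downstream observables are insensitive to this
factor.

**The nucleus** is a single rigid particle of radius
`R_nuc = R_cell · f_v^(1/3)` with `f_v = 0.10` (10 % of the cell volume,
4.64 µm).  Nucleus–cytoplasm pairs use the same potential with the distance
shifted by `R_nuc − d_eq/2`, so the surface-to-surface equilibrium gap
equals the cytoplasmic one.  Nucleus–nucleus pairs (relevant during and
after division) interact through the repulsive term only, shifted by
`2 R_nuc − d_eq`: the repulsion at equal surface gap exactly matches the
cytoplasmic repulsion and mimics mitotic spindle poles drifting apart.
Deep overlaps (shifted distance ≤ 0) are clamped to `0.05 d_eq` so they
repel strongly instead of flipping sign.

## Units

Internally: length µm, time s, energy J, force J/µm (= 10⁶ N), drag
J·s/µm².  Parameter-table values (N/m, N·s/m, Pa) are converted at the
boundary (`semcell.units`).  Per-particle virial stress is kept in energy
units (J), with no per-particle volume division.

## Dynamics

Overdamped first-order update per particle:

    dx = (dt/η) F_total + N(0, 2 a dt/η)   per component,

with `dt = 10⁻³ s` (stability requires `dt ≪ η/κ_eff`; with ~12 neighbors
the effective relaxation time is ≈ 2 ms, so 1 ms is the stable choice and
halving it changes noise-free endpoints by < 1 %).  Velocities are
previous-step finite differences (zero at t = 0); they only feed the
nuclear biasing force and diagnostics.  A step moving any particle more
than `d_eq` raises an instability error naming the particle.

**Thermal amplitude.**  No physical temperature is specified by the model;
the scenario default is `a = 0.069 u0`.  That value equals a per-step RMS
displacement of 2 % of `d_eq` for the reference `Np = 1000` cell at the
default dt, and tying it to the well depth (rather than to `d_eq`) keeps
the reduced temperature `a/u0` identical for every particle count — a
requirement for the particle-number-invariance property (the `d_eq`-tied
rule scales as `Np^(−2/3)` and melts scaled-down cells).  Both constructors
are exposed on `NoiseModel`.

**Neighbor list.**  Verlet list over a k-d tree with a 0.9 µm skin,
rebuilt when any particle moves more than skin/2; nucleus pairs are
enumerated directly (their shifted cutoffs are larger and nuclei are few).
The hot path evaluates pair forces in two numba passes around one
vectorized `np.exp`.

**Constraints.**  Plates are integrated 9-3 Lennard-Jones walls
(`V = ε[(2/15)(s/z)⁹ − (s/z)³]`, mildly adhesive, minimum at
`0.858 s`) with `ε = u0`, `s = d_eq` — only the order of magnitude
matters for plate adhesion, and both are exposed.  The pipette/channel is
a one-sided inward harmonic shell of stiffness `10 κ`.  Wall and indenter
penetration responses saturate (at `0.7 s` and 0.5 µm overlap) so stray
particles in fresh packings relax instead of being catapulted.  Bottom-slab
particles are velocity-fixed; top-slab particles share the external load
equally (`f = F_ext/N_slab`).

**The movable plate.**  A strictly static top wall would make tensile creep
impossible (the plate must travel with the stretching cell), so the top
wall tracks the mean height of the top slab at a fixed offset chosen at
t = 0: it stays adhesively coupled while exerting ~zero net force, which is
how a force-controlled plate behaves quasi-statically.

## Initial packings

The scaling relations assume densely packed particles at spacing `d_eq`;
the default preparation realizes exactly that: an FCC lattice at spacing
`d_eq` (close-packing fraction 0.74) with a small Gaussian jitter
(`0.04 d_eq`), relaxed noise-free for 200 steps.  The creep scenario
amorphizes harder (`jitter = 0.18 d_eq`, 2000 relaxation steps — a
well-annealed glass): grown, living cells are not crystals, and a
crystalline plug responds to load with brittle, bimodal failure.  An
optional `spacing_factor` packs at a multiple of `d_eq` (0.92 ≈ the
relaxed bulk density, useful for stress-field analysis).  A uniform
rejection-sampling generator (minimum spacing `0.8 d_eq`) is retained for
sparse configurations; it cannot reach nominal density (sequential
rejection saturates near 38 % fill).

A caveat this preparation makes explicit: the *bulk thermodynamic minimum*
of the truncated potential is a few percent denser than the nominal
spacing — an FCC lattice sum over the 2.5 `d_eq` cutoff has its minimum at
`0.917 d_eq`, because the attractive tails of the second and third neighbor
shells compress the first shell.  Equilibrated ensembles therefore show
their first rdf peak near `0.9 d_eq` rather than at `d_eq`, at any
thermal amplitude below surface evaporation (the bulk compression is set
by the potential's tail, not by temperature).  Volume
*ratios* of the preparation (such as the nuclear excluded volume) survive
this uniform relaxation.

## Scenarios

**Creep** (`run_creep`): a plug packed in a volume-matched tube
(`r = sqrt((4/3)R³/h)`, `h = 1.5 R_cell`) between a fixed adhesive bottom
plate and the tracking top plate.  Slabs are the particle layers within
1.5 µm (10 % of the nominal height) of the 2 %/98 % height quantiles
(quantile-referenced so single stray surface particles cannot shift the
window).  At each load onset the applied stress is converted to a total
force through the projected contact area of the top slab: the 2D convex
hull of the slab particles dilated by `d_eq/2`, computed once per segment.
Axial strain is `(z(t) − z0)/z0` with `z(t)` the plate separation (mean
height of the top slab minus mean height of the bottom slab, plus one
particle diameter), `z0` taken at load onset; plate separation is what the
instrument measures and is robust to individual particles pulled out of
the bulk in the flow regime.  The particle extent
(`max z − min z + d_eq`) is recorded alongside as the cell length — the
quantity used for the nucleus pre-stretch comparison.  Bundled protocols: 5 Pa for 7 s after a 3 s
hold, and 10 s hold / 30 s at 20 Pa / 30 s unload.  Replicates rotate the
initial packing about the load (z) axis — the creep geometry is symmetric
about z, so rotations about a perpendicular axis would not preserve it —
and draw fresh noise streams.

A note on the 20 Pa regime: the maximum tensile stress the pair network can
transmit is roughly `max|F_attr|/d_eq² ≈ 10 Pa`, so at 20 Pa the plug
yields and flows without a steady state — which is also the reported
behaviour of the modelled experiment.  Flow quantities measured there
(strain ratios, residuals) carry large seed-to-seed spread and are averaged
over three seeds.

**Migration** (`run_migration`): a free cell with nucleus; per step each
cell draws `Poisson(dt · Np/T_m)` turnover events — insert one particle at
the leading edge (0.9 of the maximal polarity projection, with 0.3 `d_eq`
tangential jitter, locally relaxed for 5 noise-free steps), remove the
particle with the minimal polarity projection.  Polarity default is
`persistent_random`: the direction rotates by a Gaussian angle of
std `1/persistence` rad per event.  A fixed direction makes the cell
treadmill away from its nucleus indefinitely (the drift never saturates),
while the shape-based turnover this emulates wanders; the persistence
default (5, i.e. 0.2 rad/event) was set so the no-bias nuclear drift
saturates at the cell radius, the defining property of that experiment,
and then frozen.

**Nuclear bias**: a spring-like force on the nucleus toward the cytoplasmic
centroid, `F = S m_nuc 2(Δnc − u_n dt)/dt²` — the force a Newtonian
particle would need to close the offset in one step, scaled by the
dimensionless constant `S`.  `S = 0` disables it; `S ≈ 0.3` is a weak and
`S ≈ 3` a strong bias with the printed masses (`m_p = 3.1` with its
ambiguous printed unit stored as a flag, default ng; the mass only scales
this force, and `S` is free).

**Proliferation** (`run_proliferation`): growth events (rate
`dt · Np/T_p`, current count by default → exponential growth doubling every
`T_p ln 2`) insert particles interstitially: at 0.6 of the cone-local
surface radius along a random direction, then locally relaxed.  Insertion
stacked onto the surface tip is dendritically unstable (every protrusion
becomes the preferred anchor), which is why the interstitial rule is used.
When a cell's cytoplasmic count reaches `2 Np_ref`, a second nucleus
appears at the first one's position plus a `0.1 d_eq` random offset, takes
a fresh cell id, and every cytoplasmic particle is reassigned to its
nearest nucleus; the mild nucleus–nucleus repulsion then drives the poles
apart and the per-cell bias recentres each daughter's nucleus.  The
constrained variant adds a cylindrical channel (radius ≥ cell radius)
around the growth axis.

## Mechanics observables

* **Virial stress** per particle: `σ_ab = −½ Σ_pairs r_a F_b` with the pair
  position taken relative to the pair midpoint, tension positive; in energy
  units; the kinetic term is omitted (overdamped system — the contribution
  is essentially all potential).  `σ_m = tr σ/3`.  Requires the per-pair
  force records captured on analysis frames.  Because the kinetic term is
  dropped, thermal snapshots carry a uniform tensile offset of order kT per
  particle; for weak structural signals (e.g. interior Laplace compression)
  evaluate the stress on a briefly quenched (noise-free-relaxed) snapshot.
* **Green–Lagrange strain** per particle between a reference and a current
  frame: deformation gradient from a least-squares fit over
  reference-frame neighbors within 10 µm, `E = ½(FᵀF − I)`, and the
  von-Mises shear invariant
  `γ = sqrt(E_xy² + E_xz² + E_yz² + [(E_xx−E_yy)² + (E_xx−E_zz)² +
  (E_yy−E_zz)²]/6)`.  Particles with fewer than 3 non-degenerate neighbors
  are flagged undefined; only particles present in both frames are
  analyzed (strain is ill-defined across migration turnover).
* **Radial distribution function**: pair-distance histogram normalized by
  shell volume and mean density (ideal gas → g ≈ 1); the reference volume
  defaults to the convex hull of the analyzed particles.
* **Binned stress fields**: mean `σ_m` in 1D/2D spatial bins, nucleus
  excluded, empty bins NaN-flagged, normalized by the maximum magnitude
  over non-empty bins.
* **Cell metrics**: centroid, nucleus offset `Δnc`, height, convex-hull
  volume, axial and volumetric strain against a chosen reference frame.
  The contact area uses the hull projection with a `d_eq/2` dilation — a
  deterministic stand-in for a surface-mesh projection; creep results use
  stress ratios and time courses that are insensitive to ≤ 20 % area error
  (it rescales the applied force uniformly).

## What the synthetic scenarios do and do not capture

The generator produces idealized packings (no organelles besides one rigid
nucleus, no membrane particles, single potential family) and the noise is
an uncalibrated effective temperature, so quantitative agreement with any
particular cell type is not claimed.  Creep ratios, drift plateaus and
stress-sign patterns are emergent and robust in sign; their magnitudes at
the 20 Pa flow regime fluctuate strongly between seeds.  The rdf peak of
equilibrated ensembles sits ~10 % below `d_eq` (see Initial packings): a
structural property of the truncated potential itself, documented rather
than hidden.

## Problem sizes

Default test and acceptance runs use the reference cell (`Np = 1000`,
3 seeds) for creep and migration, 60 s of simulated migration in the test
suite (100 s in the acceptance script, as in the modelled experiment), and
scaled-down cells (`Np = 60–400`) for unit tests of events and packing.

## Determinism

One `numpy` Generator per run seeds thermal noise and all event draws;
identical seed + configuration reproduce trajectories bit-for-bit.  Run
manifests (config echo, seed, version, derived constants) are written next
to every CLI output.
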