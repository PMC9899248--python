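# Methods

`vesidrop` simulates and analyzes the engulfment of liquid nanodroplets by
lipid nanovesicles with dissipative particle dynamics (DPD), at sizes that
run on a single CPU in minutes.  This note documents the model, the
numerical choices, what the synthetic generators do and do not emulate, and
the known limitations.

## Coarse-grained model

Four bead species build every system: lipid head (H), lipid chain (C),
water (W) and solute (S).  All beads share the diameter d (mapped to
0.8 nm), mass m = 1 and interact through the soft conservative force

    F_ij = f_ij (1 - r_ij / d) r̂_ij        for r_ij < d,   0 beyond,

with the amplitude matrix (k_B T / d)

    f:      H    C    W    S
      H    30   50   25   25
      C    50   10   75   75
      W    25   75   25   70
      S    25   75   70   25

Head and chain beads interact identically with W and S (f_HW = f_HS,
f_CW = f_CS), so both liquids wet the membrane equally and the droplet
contact angle is close to 90°.  The strong W–S repulsion drives
liquid–liquid phase separation; the solubility of S in W is
ζ = (f_WW + f_SS) / (2 f_WS) = 50/140 ≈ 0.357, recomputed from the
active force matrix whenever needed.

A lipid is 15 beads: a three-bead head group H–H–H and two six-bead
hydrocarbon chains attached to the first and last head bead.  Bonds are
harmonic, U = (k_bond/2)(r − l0)², with k_bond = 128 k_B T/d² and
l0 = 0.5 d.  Chain stiffness uses the cosine bending potential
U = k_angle (1 − cos(θ − θ0)) with k_angle = 15 k_B T and straight rest
geometry θ0 = π; this equals a harmonic angle of the same stiffness to
second order but stays smooth at the rest angle.  All bonded constants are
configurable (`BondedParams`).

## Thermostat and integration

The DPD thermostat adds pairwise dissipative and random forces on the same
cutoff, with weight functions w_D = (1 − r)² and w_R = (1 − r), friction
γ = 4.5 (m/τ units) and noise amplitude fixed internally by
fluctuation–dissipation, σ² = 2 γ k_B T.  The random number for a pair at
a step comes from a counter-based hash of (seed, step, i, j) with i < j,
so forces are independent of iteration order and bit-reproducible; the
uniform variate is scaled to unit variance.  Time stepping is the standard
DPD velocity-Verlet (half kick, drift, force evaluation with half-kicked
velocities, half kick) at dt = 0.01 τ.  γ, dt and m are conventional
stable values for these force amplitudes, not quantities the reference
system pins down.  Measured consequences at these settings: the kinetic
temperature settles about 0.5 % above k_B T (the known velocity-Verlet
artifact of DPD), and bulk water at ρ = 3/d³ shows an excess virial
pressure of ≈ 20.7 k_B T/d³.

Pair search uses a cell list (cell edge ≥ d) rebuilt every step by
counting sort, with beads gathered into cell order for memory locality;
boxes too small for three cells per axis fall back to the exact O(N²)
loop, which doubles as the test oracle for the cell path.  A step in which
any bead would move farther than d/2 aborts with an unstable-timestep
diagnostic.

Physical time: τ = d sqrt(m / k_B T) is the intrinsic unit.  A mapping to
microseconds requires an explicit user-chosen time-scale factor on top of
d = 0.8 nm; none is built in because no such factor is derivable from the
model itself.

## Assembly and bookkeeping

Vesicles are assembled as two spherical leaflets on Fibonacci-sphere
lattices: inner-leaflet heads face the lumen, outer-leaflet heads the
exterior, chains interdigitate toward the midsurface with a 0.6 d gap
between leaflet chain tips.  Each monolayer spans 2.5 d radially as
assembled.  Placement jitter is tangential only, preserving the radial
bead stacking, and the shell is relaxed by capped-displacement
minimization (default 300 steps, cap 0.05 d) before dynamics; built
systems have no nonbonded pair closer than 0.3 d.  A leaflet whose area
per lipid falls below 0.55 d² (or above 2.6 d²) is rejected.

Reduced-scale vesicles preserve the full-scale areas per lipid
(1.14 d² outer, 1.02 d² inner head layer) at fixed bilayer thickness;
plain sqrt(N) scaling of the diameter would overfill the inner leaflet at
small lipid numbers because the bilayer thickness does not scale.  The
default reduced system (1,000 lipids) has an outer diameter of ≈ 17.4 d.

Droplets start water-free: N_S solute beads packed at bulk density into a
sphere of radius (3 N_S / 4πρ)^{1/3} = (N_S / 4π)^{1/3} d.  Solvent
filling tops the box up to exactly round(ρV) beads total on a jittered
cubic lattice, excluding a clearance shell around every existing bead
*and* the regions enclosed by membranes or droplets (a pure nearest-bead
exclusion is not sufficient: lattice interstices inside a dense bead
packing pass it).  Every builder returns an exact census
(lipid beads, interior W, exterior W, S, total) and the solute mole
fraction Φ_S = N_S / (N_S + N_W^ex).

Vesicle volume is tracked by ν = N_W^in / N_W^isp, the interior water
count relative to the freshly assembled sphere.  Osmotic deflation moves
exactly round(Δν · N_W^isp) interior water beads to voids in the exterior
solution; species counts are conserved bead for bead.  Interior and
exterior water are distinguished by connectivity of the W proximity graph
(cutoff 1 d): an intact bilayer disconnects the lumen from the bulk, and
a singly connected water phase is reported as a membrane pore and aborts
deflation.  This graph criterion replaces ray-parity against a
triangulated midsurface: it gives the same verdict for closed membranes
of any shape and detects leaks for free.

## Stress profiles and tensions

All tensions are integrals of s = P_N − P_T, the difference between
normal and tangential components of the local pressure tensor.

* Spherical (vesicles): shells of width 0.2 d about the lipid center of
  mass (recomputed each frame; an externally supplied center errors out
  if the membrane drifts > 1 d from it).  Bilayer tension
  Σ = ∫ s(r) dr; the leaflet tensions Σ_il, Σ_ol split the same bin sums
  at the midsurface radius R_mid, located at the peak of the chain-bead
  density, so Σ = Σ_il + Σ_ol holds to machine precision by construction.
* Planar (slabs): slices along the interface normal; the per-interface
  tension divides the integral by the number of interfaces (two for a
  periodic slab).  A minority-phase slab touching both box faces along
  the normal is rejected as wrapped.
* Axisymmetric (vesicle–droplet couples): a cylindrical (r, y) grid with
  mesh d about the symmetry axis; s = P_yy − (P_rr + P_φφ)/2, the axial
  component minus the mean of the two transverse cylindrical components.
  Segment and interfacial tensions are line integrals of s across the
  respective surface segment inside labeled rectangular integration
  boxes, which must be disjoint and non-empty; the analysis refuses
  states that fail the axisymmetry check.

The pair virial is assigned in space along the straight interbead segment
(Irving–Kirkwood contour): radial and cylindrical binning subsample the
segment at 20 points with weight 1/20; planar binning distributes it over
slabs in exact proportion to overlap length, which makes the summed slab
virial equal the direct all-pairs virial identically.  Three-body bending
forces are decomposed onto the two arm segments (central-force
decomposition).  Only conservative and bonded forces enter the virial —
the thermostat pair forces time-average to zero and their omission makes
the analysis of a stored frame deterministic.  Kinetic contributions are
accumulated per bead.  The Harasima contour is not implemented.

Statistical errors are standard errors over five block averages of the
frame series.

## Morphology

* Droplet size: diameter from the half-maximum of the radial S-bead
  density about the majority S cluster (clusters from the bead proximity
  graph at cutoff 1 d); asphericity from the gyration-tensor invariant,
  zero for a sphere.
* Contact line: membrane head beads within 1 d (the force cutoff) of
  both the droplet phase and the exterior bulk phase.  The point set is
  ordered by nearest-neighbor chaining with a limited 2-opt repair,
  giving the length L_cl, the enclosed area in the best-fit plane, and
  the circularity 4πA/L² (1 for a circle).  States with circularity
  ≥ 0.95 count as axisymmetric, and only then is R_co (mean centroid
  distance) reported; a 2:1 ellipse (circularity 0.84) already fails the
  threshold, and tight-lipped stadium shapes fall below 0.6.  If no head
  bead touches both phases the neck has sealed and a closed-neck
  indicator is returned instead.
* Contact angles (axisymmetric states): the symmetry axis is the normal
  of the contact band's best-fit plane through the center of an in-plane
  circle fit (a plain centroid is biased by azimuthal sampling noise).
  In the (r, y) half-plane the droplet interface and the adjacent
  membrane segment are each fitted by a local quadratic in a frame
  aligned with the point cloud's principal direction, inside a 3 d
  window of the contact point; the contact point is refined as the
  intersection of the two fitted curves (three passes).  Algebraic
  circle fits were rejected: on arcs a few d long with 0.1 d noise the
  sagitta is of the order of the noise and the Kasa fit collapses to
  spurious small circles, while the rotated-frame quadratic recovers
  tangents to better than 2°.  θ_α* is the angle between the two fitted
  tangents oriented into their surfaces (measured through the droplet
  phase); ψ_co is the membrane tangent's tilt against the contact-line
  plane.
* Engulfment state: `fission` if the lipid-bead proximity graph has two
  or more connected components; otherwise `free` (no solute–lipid
  contact), `complete-closed-neck` (no solute bead within 1 d of
  exterior water — the defining condition of a sealed neck), or
  `partial-open-neck`.  Interface and contact areas are estimated as
  contact-bead counts times ρ^{-2/3}.

## Wetting theory

The isoperimetric inequality A³ ≥ 36πV² bounds complete engulfment: for
inner-leaflet segment areas A_αγ, A_βγ enclosing the droplet volume V_α
and the interior volume V_γ, engulfment requires both
A ≥ (36π)^{1/3} [V_α^{2/3} + (V_α + V_γ)^{2/3}] and
V_α ≤ (A_αγ + A_βγ)^{3/2} / (2^{3/2} (36π)^{1/2}) = V_α^max, the
V_γ = 0 limit where the inner leaflet forms two touching nested spheres.

The contact-line tension follows from the tangential force balance along
a circular contact line,

    Σ_βγ − Σ_αγ = Σ_αβ cos θ_α* + (λ / R_co) cos ψ_co,

solved for λ, with first-order error propagation assuming independent
inputs (they come from separate estimators).  The balance is refused when
|cos ψ_co| < 0.05 (the line-tension force has no in-plane component) and
assumes both membrane segments share the same curvature-elastic
properties; no correction for unequal segments is applied.

## Synthetic generators

The fixture module generates every analysis input with machine-readable
ground truth: ideal-gas boxes (zero excess pressure), frozen two-bead
systems (single-pair virial f(1−r)r), planar S-in-W slabs with exact bead
bookkeeping, loops with analytic circularity (circle; ellipse via the
complete elliptic integral; stadium for the tight-lipped morphology),
mock axisymmetric vesicle–droplet surfaces built from spherical caps and
a torus arc whose closed-form tangents realize prescribed
(θ_α*, ψ_co, R_co) — parameter pairs with θ_α* − ψ_co ≤ 2° are rejected
as self-intersecting — and constructed engulfment topologies (nested
shells for fission, a wrapped droplet for the closed neck).  Fixtures are
deterministic given their seed.

What they do not emulate: dynamics (no time-correlation structure), the
fluctuation spectrum of real interfaces (mock surfaces carry isotropic
Gaussian noise), lipid conformational disorder, or finite-concentration
solute exchange.  Tests passing on fixtures therefore validate the
estimators' geometry and bookkeeping, not the thermodynamics of real
trajectories; the small simulations in the test suite cover the latter at
reduced scale.

## Problem sizes and reproducibility

The bundled measurement scripts run: bulk water pressure on 3,000 beads
in a (10 d)³ box (10⁴ production steps); the planar interfacial tension
on a 10 d slab in 16×16×32 d³ (24,576 beads); the droplet diameter with
5,400 solute beads in a (30 d)³ box (81,000 beads); and reduced vesicles
of ~800–1,000 lipids for the membrane-tension machinery.  These sizes
give few-percent statistics for the bulk quantities while remaining
single-CPU jobs.  All randomness flows from explicit seeds: identical
seed and configuration reproduce a trajectory bit for bit on a platform;
analysis of stored frames is platform-independent pure arithmetic.

## Known limitations

* Reduced-box droplet sizes sit slightly above the large-box reference:
  in a small box almost no solute remains dissolved in the bulk phase, so
  the condensed droplet retains nearly all N_S beads.
* Leaflet-tension sign structure at reduced scale is reported, not
  asserted: at ~1,000 lipids the inner leaflet is small and highly
  curved, and the assembled (rather than annealed) leaflet populations
  need cluster-scale statistics to pin the tensionless point.
* The engulfment protocol classifies states between deflation stages; it
  does not attempt the multi-microsecond neck-closure and fission
  kinetics at full scale.
* NVT only (the model's bulk pressure is set by the density convention);
  no electrostatics; single lipid component.  A solute–membrane affinity
  contrast (f_HW ≠ f_HS) is accepted by the force-field container but
  untested against any reference behavior.
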