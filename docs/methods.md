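# Methods

This note documents the model, the numerical choices and the calibration
behind `memrod`, and states what the desk-scale tests do and do not show.

## The model

### Membrane

The membrane is an implicit-solvent, meshless single-layer fluid: `N`
particles with positions `r_i` and unit orientation vectors `u_i` (the
local membrane normal), interacting through

```
U = U_rep + U_att + U_bend + U_tilt
U_bend/kT = (k_bend/2) Σ_{i<j} (u_i − u_j − C_bd r̂_ij)²  w_cv(r_ij)
U_tilt/kT = (k_tilt/2) Σ_{i<j} [(u_i·r̂_ij)² + (u_j·r̂_ij)²] w_cv(r_ij)
```

with `k_bend = k_tilt = 10` and membrane spontaneous curvature zero
(`C_bd = 0`).  Lengths are in units of the particle diameter σ and energies
in k_BT (both 1).

`U_rep` and `U_att` are the free part of the model family.  We use

* `U_rep = ε_rep Σ_{i<j} exp[−α(r_ij − 1)] f_c(r_ij; 1.2σ)` — a steep
  exponential core (α = 20) with a smooth compact cutoff,
* `U_att = ε_att Σ_i ψ(ρ_i)`, `ψ(ρ) = ¼ ln[1 + e^{−β(ρ − ρ*)}]`, with the
  weighted local density `ρ_i = Σ_j f_ρ(r_ij; 1.9σ)`.  ψ decreases linearly
  in ρ below the saturation density ρ* and flattens above it, so the
  membrane condenses into a two-dimensional fluid sheet but does not
  collapse into a three-dimensional aggregate,
* all compact weights (`f_c`, `f_ρ`, `w_cv`) use the same C∞ form
  `exp[a(1 + 1/((r/r_c)^n − 1))]` that vanishes with all derivatives at its
  cutoff.

The free coefficients are fixed by calibration against the membrane's
emergent elastic constants (below); the shipped values are in
`src/memrod/data/params_canonical.yaml` (ε_rep = 4, α = 20; ε_att = 2.5,
β = 6, ρ* = 7.68, density weight cutoff 1.9σ; w_cv cutoff 2.4σ with n = 4,
a = 2).

### Protein rods

A crescent protein (BAR-domain style, modeled together with its bound
membrane patch) is a chain of 10 membrane particles connected by harmonic
bonds (rest length 10σ/9, so the rod spans `r_rod = 10σ`), with the stiff
bend/tilt coefficients `k_rod = 80` and a spontaneous curvature `C_rod`
along the backbone.  Rod backbone particles remain ordinary membrane
particles for the repulsion/attraction terms.

`C_rod` is imposed through the pair parameter `C_bd` of the intra-rod
bend/tilt terms.  Rather than reusing the membrane relation
(`C_0 σ = C_bd/2`, which is specific to the 2D sheet), the map
`C_bd(C_rod)` is computed numerically: the intra-rod bend+tilt energy
restricted to circular arcs is minimized over the arc curvature, and C_bd
is chosen (by a secant iteration on the linear map) so the minimum falls at
`C_rod` to 0.1%.  For the default geometry this gives
`C_bd ≈ 1.15 C_rod σ`.

Chirality is purely steric: two hook particles are added between the first
and second particles of both rod ends, each at one bond length from both
anchors.  The hook offset from the anchor midpoint combines a lateral
in-plane component (perpendicular to the backbone; its sign pattern over
the two ends distinguishes the chiral rod from the achiral hooked
reference) and an out-of-plane elevation of 60° along the membrane normal
— the protein protrudes on the bound side of the membrane, and the
elevation is also what makes it possible to insert hooks into a dense
sheet.  Hooks interact with everything through excluded volume only; the
three bonds of each hook triangle (hook–anchor ×2 plus the anchor–anchor
backbone bond) carry a 3× stiffened coefficient.  The backbone bond
stiffness is 2500 kT/σ² (bond-length fluctuations < 2%), a documented
default.

Flipping a hook to the mirror (left-handed) site is blocked kinetically:
the direct path stretches the 3× triangle bonds by tens of k_BT, and the
rotation path sweeps the hook through the membrane sheet the rod is bound
to (the test suite measures both barriers).

With the side-to-side attraction switched on (ε > 0), the excluded-volume
term is replaced by a Lennard-Jones potential `4ε[(σ/r)¹² − (σ/r)⁶]`
between inter-rod pairs of the 2nd/3rd particles from both rod ends
(segments {1,2,7,8}, 0-based), smoothly switched off between 2σ and 3σ.

## Dynamics

Translations are underdamped Langevin dynamics (BAOAB splitting).
Orientations are rigid linear rotors: an angular velocity ω_i ⊥ u_i (two
rotational degrees of freedom) feels the torque `−u×∂U/∂u`, friction and
matched noise, and u_i is rotated exactly about ω_i, so |u_i| = 1 to
machine precision indefinitely.

Defaults: mass = inertia = 1, dt = 0.004 σ(m/kT)^½ for membrane-only runs
and 0.002 with rods (the stiff bonds), frictions γ_t = γ_r = 0.5 (0.25 in
assembly runs).  The low friction is deliberate: equilibrium averages do
not depend on γ, and smaller γ maximizes diffusion per step.  At the
calibrated state point the membrane is a dense 2D liquid (hexatic order
parameter ≈ 0.2) with in-plane diffusion D ≈ 0.006–0.01 σ²/t, so the
intrinsic time unit τ = r_rod²/D corresponds to ~10⁶ MD steps.  All
physical results are reported against τ, never against the step count, so
the friction and time step drop out.

A per-particle force cap (default 10⁴ kT/σ) limits the displacement caused
by rare deep-overlap spikes in dense initial conditions; configurations
that high in energy are never sampled in equilibrium, so the cap does not
affect averages.  It can be disabled (`f_clamp = 0`), as the
energy-conservation test does.

### Zero-tension ensemble

The tensionless flat membrane is sampled by interleaving Langevin dynamics
with Metropolis Monte-Carlo area moves: symmetric proposals in ln A
(rescaling x, y and the box) accepted with probability
`min(1, exp(−βΔU + (N+1)Δln A))`.  This samples the exact zero-tension
ensemble, so both the mean area (→ a₀) and the area fluctuations (→ K_A)
are meaningful — a deterministic rescaling controller would distort the
fluctuations.  A Berendsen-style `rescale_area` is still provided for
quick relaxations.  The virial route to the in-plane tension
(γ = −[NkT + (W_xx+W_yy)/2]/A) is used for the strain-route K_A and for
the stretched/compressed sign checks.

### Replica exchange

Hamiltonian replica exchange over C_rod at a single temperature: adjacent
replicas swap labels with probability `min(1, e^{−ΔU})`,
`ΔU = [U_a(C_b) + U_b(C_a)] − [U_a(C_a) + U_b(C_b)]`, evaluated from the
intra-rod bend/tilt terms only (the only C_rod-dependent part of the
Hamiltonian).  The default ladder is uniform in `C_rod·r_rod` with spacing
0.25 over [0, 3.5]; the number of replicas and the exchange interval are
configurable and scale-dependent.

## Observables

* Fourier modes on tubes: `r_qz = (1/N) Σ r2D,i e^{−i2πz_i/L_z}` and
  `r_qθ = (1/N) Σ r2D,i e^{−2iθ_i}` with θ from the two-argument
  arctangent of (x, y) and the axis recentered on the in-plane center of
  mass.  Shape modes run over all non-hook particles; rod density modes
  (`n_qz`, `n_qθ`) are the same sums over rod backbone particles.  The qθ
  mode uses angular wavenumber 2, so the elliptical (two-fold) deformation
  maximizes it.  "Starred" values are normalized by the C_rod = 0 run of
  the same geometry.
* Helical-assembly radius `R_hel`: mean in-plane distance of rod backbone
  particles from the slice center of mass, over the axial slice of width
  0.4 r_rod centered (circularly) on the rod assembly.
* Cluster statistics: two rods connect when any inter-rod backbone pair is
  within 1.25σ (just outside the hard core); single-linkage components.
  Both the per-rod mean (ΣN²/ΣN) and the per-cluster mean (ΣN/#clusters)
  are computed; the per-rod mean is the default.
* Membrane span: rms z of membrane particles about their mean plane.
* Shape classifier: `elliptical` when |r_qθ|/⟨r2D⟩ > 0.12;
  `helical_cylinder` when the cross-section stays round while the dominant
  rod cluster holds ≥ 50% of the rods and winds ≥ 1.5π of accumulated
  azimuth along z; `cylindrical` otherwise, `ambiguous` when both fire.
  Thresholds are package constants (`ShapeThresholds`), documented, and
  deliberately coarse — they label morphologies, not free-energy basins.

## Calibration of the elastic constants

The four membrane observables that define the model are the area per
particle of the tensionless membrane `a₀`, the area compression modulus
`K_A`, the bending rigidity `κ` and the edge line tension `Γ`.

* `a₀`: time-averaged projected box area / N in the zero-tension ensemble.
* `K_A`: fluctuation route `kT⟨A⟩/Var(A)` from the same run, cross-checked
  against the strain route (slope of tension vs areal strain at fixed box).
* `κ`: height-fluctuation spectrum of a fixed-box patch pre-equilibrated
  to the tensionless area.  Heights are binned to a ~1.8σ grid,
  `kT/S(q) = γq² + κq⁴` is fitted after discarding the two smallest-q
  shells and everything above q = 1/σ (protrusion regime).  The estimator
  is validated by a parameter-recovery oracle on synthetic height fields
  drawn from a known κq⁴ spectrum.
* `Γ`: a membrane strip spanning the periodic x direction with two free
  edges pulls along x with force 2Γ.  The estimator uses the pair-virial
  stress anisotropy `(W_yy − W_xx)/L_x`, which cancels the isotropic
  membrane contribution (free edges enforce ⟨NkT + W_yy⟩ = 0), and the
  strip is built at the model's own a₀ and weakly confined along z
  (z-only force, no in-plane virial) to suppress slow flapping modes.
  Even so the edge modes are slow; single strip runs scatter by ±2 kT/σ at
  desk scale, and Γ is only pinned down by averaging several seeds.

`calibrate()` is a diagonal derivative-free loop: each free coefficient is
driven by one target through a secant/power update until all targets agree
within tolerance or a budget is exhausted.  The shipped canonical set was
produced this way against the targets (a₀ = 1.2778 σ², K_A = 83.1 kT/σ²,
κ = 15 kT, Γ = 5.73 kT/σ) and measures, at desk scale (N = 512–1024):

* a₀ = 1.277 ± 0.001 σ²,
* κ = 15.8 ± 0.7 kT,
* Γ = 5.9 ± 0.8 kT/σ (seed scatter),
* K_A ≈ 70–80 kT/σ² depending on run length — the weakest constant of
  this potential family.  Longer runs include slower area modes and push
  the fluctuation estimate down; no coefficient combination we explored
  raises K_A to 83 without breaking a₀ or Γ.  The package reports what it
  measures.

## Desk-scale physics tests: what they show

The membrane's intrinsic time τ ≈ 10⁶ MD steps puts the full assembly and
tubulation phenomenology (hundreds of τ) outside a desk budget.  The test
suite therefore checks the *mechanisms* at reduced scale:

* azimuthal ordering precedes longitudinal: an elliptically deformed tube
  whose high-curvature edges carry azimuthally wrapped rods sustains its
  two-fold azimuthal shape mode |r_qθ| (and a dominant azimuthal rod
  density mode), while the identical membrane without rods relaxes back to
  a circular cross-section; the longitudinal modes stay at their noise
  floor throughout;
* chirality controls the helical cylinder: chiral rods sustain a pre-built
  packed helical wrap (the protocol of the canonical helical-assembly
  runs); achiral rods started from generic embeddings at the same high
  C_rod are never classified as a helical cylinder;
* the relaxed helical-wrap radius R_hel decreases monotonically with
  C_rod and stays above the preferred radius 1/C_rod (rods are not rigid);
* the side-to-side attraction deepens the quenched energy of a
  membrane-embedded side-by-side rod pair by ~15 k_BT (paired double
  difference against separated rods) and keeps a packed helical band
  classified helical at the low curvature C_rod·r_rod = 2 — the mechanism
  by which it extends the helical phase to lower curvature.  The full
  phase-boundary shift is an equilibrium statement beyond desk reach;
* in early-time tubulation runs the chiral and achiral cluster-growth
  curves coincide within seed error while the chiral membrane span grows
  at least as fast (the chirality-driven speedup of tubule protrusion
  itself lives at much later times).

Pre-built (fixture) initial states stand in for equilibration where noted;
passing these tests shows the energetics and the measurement chain are
right, not that the full phase diagram is reproduced.  The fixtures are
generated by code (`memrod.io.make_fixture`), never stored.

## Known limitations

* K_A sits ~10% below the target value (above).
* No hydrodynamics; Langevin friction sets the (arbitrary) time scale.
* The zero-tension ensemble applies to flat patches only; tube runs fix
  L_z with a free radius.
* Checkpoint restarts are exactly reproducible against each other, and
  match an uninterrupted run to floating-point roundoff (summation order
  inside the force kernel depends on array alignment, which an HDF5
  round-trip cannot preserve).
* The classifier thresholds are morphological conventions; near phase
  boundaries it reports `ambiguous` rather than forcing a label.
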