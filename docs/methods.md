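# Methods

`condcap` models the self-assembly of icosahedral virus capsids inside a
biomolecular condensate that is represented *implicitly*: a spherical
attractive potential well rather than explicit condensate molecules.  The
package has four layers — coarse-grained subunit models, a rigid-body
Langevin engine, equilibrium and kinetic theories of condensate-coupled
assembly, and trajectory analytics — and this note records the model
definitions, parameter choices, and numerical decisions behind each.

All quantities are in reduced units: energy in kT, mass in subunit
masses, length in the subunit length scale (`l0` for the pentagonal
model, `sigma` for the triangular model), time in `t0 = l0 sqrt(m/kT)`.

## Subunit models

**Dodecahedron model.**  A rigid pentagonal subunit with circumradius
`l0` carries five attractor (`A`) pseudoatoms at the pentagon vertices,
one top (`T`) sphere at height `h_T = 0.5 l0` above the pentagon plane on
the symmetry axis, and one bottom (`B`) sphere at `h_B = 0.25 l0` below
it.  Twelve subunits tile the faces of a regular dodecahedron; in the
closed shell, neighbouring pentagons share both vertices of an edge, so
matching attractors *coincide*.  Consequently the `A`–`A` Morse
attraction has its minimum at contact (`r_eq = 0`); a complete bond
(one shared edge) is two attractor contacts.

* Morse range: `alpha_M = 5 / l0`, cutoff `r_cut = 1.9 / alpha_M = 0.38 l0`,
  cut and shifted.  With this cutoff one bond is worth
  `2 x 0.723 eps_ss ~ 1.45 eps_ss` (8.7 kT at `eps_ss = 6`).  The range
  and cutoff were calibrated against the package's own scaled assembly
  runs at `eps_ss = 6` in a condensate: longer cutoffs (`0.4-0.5 l0`,
  bonds 1.50-1.69 eps_ss) over-nucleate and trap fused, overgrown
  aggregates before shells can close; shorter ones (`<= 0.35 l0`,
  <= 1.37 eps_ss) fail to nucleate on accessible timescales.  The chosen
  value closes complete shells at `eps_ss ~ 6-7` with malformed
  aggregates taking over at larger binding strengths, the qualitative
  regime structure the models are designed to exhibit.
* `T`–`T` WCA: diameter derived from the closed-shell geometry — top
  spheres of bonded neighbours sit at separation
  `2 (phi^2/2 + h_T) sin(31.72 deg) = 1.902 l0` in the capsid, and the
  cutoff lands (with 0.5% slack) just inside this distance, leaving the
  assembled shell exactly unfrustrated (zero repulsive energy, every
  attractor pair at its minimum — both asserted in the test suite).
  Because the top spheres *approach* each other as a bonded hinge opens
  toward flat (1.90 to 1.62 `l0`), this repulsion doubles as the
  dihedral spring selecting the capsid curvature.  Its amplitude is a
  calibrated parameter: at 1 kT the spring is so soft (~0.05 kT per
  30 deg of opening) that scaled assembly runs terminate in
  curvature-mismatched 13-14-subunit shells, while at the default 8 kT
  the same opening costs ~1 kT and twelve-subunit shells close cleanly.
* `B`–`T` WCA diameter `1.0 l0`: blocks face-to-face ("upside-down")
  binding, in which the flipped subunit's `T` sphere comes within
  `0.25 l0` of the partner's `B`.
* Inertia: seven equal point masses summing to 1; the body frame
  (centroid at origin, face normal along +z) is a principal frame.

**Icosahedron model.**  A rigid triangular subunit of circumscribed
diameter `3 sigma` carries 45 excluder (`EXC`) pseudoatoms on a
single-layer triangular grid (9 rows) inset `0.31 sigma` from the
binding edges, plus six attractors, two per edge at one and two thirds
of the edge length, offset `0.30 sigma` into the face.  Edge `k` carries
tags `Ak` and `Bk`; only A-type/B-type pairs attract (Lennard-Jones,
well depth `eps_ss`, `sigma_LJ` chosen so the minimum sits exactly at
the attractor separation realized at the icosahedral dihedral angle of
138.19 deg, cutoff `2 sigma_LJ`).  This lock-and-key pairing means two
edges bind only in the back-to-back orientation with the correct
curvature sign.  The excluder contact diameter is `0.5 sigma`, sized so
edge-adjacent excluder rows of neighbouring shell faces just clear each
other at the target dihedral.  All three edges are equivalent, as
appropriate for a T=1 shell of identical subunits.  The icosahedron
model is exercised by the geometry and analytics layers; its assembly
*kinetics* have not been calibrated the way the dodecahedron model's
have, and the single-layer excluder plate is thin, so dynamics runs with
it should be treated as exploratory.

## Condensate field

The condensate is a sphere of radius `R_c` pinned at the box center:
`u_c = -eps_c` inside, and a Morse-tail decay
`-eps_c (2 e^{-a x} - e^{-2 a x})`, `x = r - R_c`, `a = alpha_C = 10`
(inverse length) outside, giving a continuous potential with gradient
bounded by `alpha_C eps_c / 2`.  The field couples once per subunit at
its center of mass, so an n-subunit cluster gains `n eps_c` by entering
the droplet.  The condensate is **not** wrapped periodically; runs
require `R_c` + interaction range < `L/2`.  When concentration scans
change the box at fixed volume ratio `V_r = V_c/V_bg`, `R_c` rescales
with `L` so that `V_r` stays fixed.

## Langevin engine

Translational and rotational Langevin dynamics with a BAOAB splitting:
half kick, half drift, exact Ornstein–Uhlenbeck velocity/angular-momentum
refresh, half drift, force refresh, half kick.  Rotations use the
"no-squish" exact free-rotor factorization (axis sequence 3-2-1-2-3) on
unit quaternions with per-substep renormalization; with zero friction
the integrator is symplectic NVE (energy drift < 1e-3 over 1e4 steps at
`dt = 1e-3` for a bonded dimer, asserted in the acceptance suite).

* Defaults: `dt = 5e-3`, `gamma = 1` (so the free-subunit diffusion
  constant is `D = kT/gamma = 1`, verified against the Einstein relation
  to 5%), isotropic rotational friction `gamma_rot = gamma x
  circumradius^2`, temperature 1.
* Pair forces run over an atom-level Verlet list built from a cell list
  with per-type-pair list cutoffs (`r_cut,ij` + skin); the default skin
  is 0.7, with rebuilds when any body's translation plus rotation arc
  exceeds half the skin.  A skin of 0.4 was measured to spend more time
  rebuilding than it saves in pair pruning for these strongly rotating
  bodies, which is why the default deviates from the smaller
  conventional choice.  Neighbor-list forces agree with an all-pairs
  reference implementation to 1e-10.
* Thermostat noise is pre-drawn in bulk by a seeded PCG64 generator and
  passed into the kernel, which makes trajectories bit-reproducible for
  a given (seed, configuration, platform) and keeps the per-step RNG
  cost negligible.
* Random initialization rejection-samples non-overlapping circumspheres
  (1e4 retries per subunit) with uniform orientations and
  Maxwell–Boltzmann momenta.

## Equilibrium theory

The two-state theory allows only free monomers and complete capsids of
`N_cap` subunits.  In each phase, mass action fixes
`mu_cap = N_cap mu_1`; across phases each species' chemical potential is
equal; total mass is conserved.  Because a capsid couples to the field
with `N_cap eps_c`, the field term cancels from in-phase mass action —
condensates enhance assembly purely by concentrating monomers.

* **Ideal mode:** `mu = ln rho` (thermal-wavelength factors absorbed
  into `dG_cap`, so densities are bare reduced number densities);
  partition coefficient `K_c = e^{eps_c}`.
* **Hard-sphere mode:** monomers and capsids are effective hard spheres
  (`sigma_sub`, `sigma_cap`); excess chemical potentials come from the
  Carnahan–Starling equation of state and its binary-mixture (BMCSL)
  extension, implemented as the analytic derivative of the BMCSL free
  energy (verified symbolically to reduce to CS for equal diameters).
  The CS form is unreliable above packing fraction ~0.5 and the code
  warns there; solutions with total packing >= 0.74 are rejected.
* **Solver:** the problem reduces to one bracketed root find on the
  common monomer chemical potential; each evaluation solves the
  per-phase composition by two nested bracketed roots that are monotone
  by convexity of the mixture free energy.  (A naive nesting that fixes
  the monomer *density* and solves mass action for the capsid density
  loses the convexity guarantee and genuinely has no root near the
  packing limit.)  Relative tolerances 1e-10; mass conservation holds to
  1e-10 in the returned solution.
* **Effective diameters:** `sigma_cap = 5.1` for the dodecahedron model
  (the literature estimate for this shell; the close-packing
  concentration can also be overridden directly with the printed value
  1.28e-2, which corresponds to a slightly smaller effective diameter).
  `sigma_sub` defaults to an orientation-averaged Mayer (Barker–
  Henderson-style) diameter computed from the repulsive pair rules,
  `d^3 = 3 int (1 - <e^{-u}>) r^2 dr` — about 1.80 `l0` for the default
  pentagonal subunit.  The circumscribing-sphere diameter (2.6 `l0`)
  badly overestimates excluded volume because the vertex attractors
  carry none; the Mayer construction reproduces the model's repulsive
  second virial coefficient exactly, which is the property the
  low-density theory actually depends on.
* **Capsid free energy:** `dG_cap = -n_bonds (eps_bond - T ds_bond)`
  with `eps_bond` measured from the pair-potential minimum of one
  complete bond and a single per-bond entropy penalty `ds_bond`
  (default 6.14 kT) calibrated so that the bulk critical subunit
  concentration at the reference strength `eps_ss = 6` equals 1e-3
  (`rho_CSC = exp(dG/(N_cap-1))` convention), the concentration scale at
  which condensate-free assembly first becomes productive.  Both the
  penalty and the estimator are configurable.

With these inputs the hard-sphere theory places the yield optimum at
`rho_T ~ 3.8e-4` for `eps_ss = 6`, `eps_c = 7`, `V_r = 5e-3`, and the
condensate capsid density saturates around 0.77 of close packing at
`rho_T = 1e-3` — the excluded-volume phenomenology the theory exists to
capture, with the caveat that the optimum's location inherits the
`ds_bond` calibration.

## Kinetic estimates

Closed-form scalings, not rate-equation integrations: the condensate
filling time `tau_D = [V_c/(V_r + 1/K_c) + f_c V_tot]/(4 pi R_c D)`
(Smoluchowski flux onto the droplet), the nucleation speed-up
`s_nuc = V_r (V_r + 1/K_c)^{-n_nuc}`, and the median assembly time
`tau_1/2 = tau_1/2^0 / s_nuc + tau_D/2`.  The speed-up expression is
grouped with the exponent on the concentration-amplification factor
`(V_r + 1/K_c)^{-1}` — the only grouping under which partitioning
*accelerates* nucleation.  The critical nucleus size defaults to
`n_nuc = 5` and is treated as condition-independent; `K_c` may be the
equilibrium value or a measured, time-dependent one.

## Trajectory analytics

Bond criteria: pentagon edge midpoints within `0.3` (dodecahedron);
both attractor pairs of an edge pair within `1.3` (icosahedron);
minimum-image throughout.  Each subunit edge joins at most one bond
(nearest candidate wins), so node degree cannot exceed the bond-site
count.  Clusters are connected components; complete = `N_cap` subunits
all at maximal degree; dangler = `N_cap` subunits but fewer bonds;
malformed = dangler, oversized, or over-bonded.  Condensate membership
of a cluster is decided by its minimum-image-consistent centroid.
The median assembly time interpolates linearly between snapshots (so it
carries a +/- one-snapshot-interval uncertainty); the maximum assembly
rate convolves the yield series with a reflect-padded first-derivative
Gaussian (default width 10 snapshot intervals).  Replicates aggregate as
mean +/- twice the standard error of the mean.

## Synthetic fixtures

The fixture generators plant known ground truth for the analytics:
isolated-monomer gases (pair distances > 3 circumradii), exact reference
capsids, danglers built by hinging the last subunit about one bonded
edge (12 subunits, 26 of 30 bonds), and condensates packed with complete
capsids on an FCC lattice, where a requested packing fraction is
realized by placing the `round(eta V_c / v_cap)` lattice sites nearest
the center (exact to the one-capsid quantization).  Fixtures exercise
classification and bookkeeping only; they make no statement about
dynamics, and passing fixture tests shows the analytics are correct, not
that the physics is.

## Scaled study conditions

Production-scale studies of this class of models run 1e6 time
units with 1200 subunits.  The package's default test and example runs
are deliberately desk-scale, chosen up front from the diffusion-time
estimate above: at `N = 60-100`, `rho_T = 4e-4`, `V_r = 5.03e-3` and
`D = 1`, `tau_D ~ 4e3`, so runs of `t_F = 6e3–8e3` capture the
condensate-filling and early-assembly regime.  At this scale,
condensate-coupled runs at `eps_ss = 6`, `eps_c = 7` nucleate within a
few thousand time units while condensate-free runs stay monomeric, which
is the contrast the scaled acceptance run asserts.  Two caveats are
inherited from the scale reduction: yields are quantized in units of
`N_cap/N`, and the condensate holds only a handful of capsids' worth of
material, so partially assembled intermediates and shell-shell
collisions weigh more heavily than at production scale — replicate
scatter is correspondingly larger.

## Known limitations

* Subunits are perfectly rigid; no intra-subunit flexibility.
* The condensate neither grows, deforms, nor moves, and its
  constituents are not modeled; subunits do not feed back on phase
  coexistence.
* The two-state theory has no intermediates; the CS/BMCSL equations of
  state degrade above packing fraction ~0.5, exactly the regime the
  saturating condensate approaches.
* Empty capsids only: no genome or cargo.
* Single-machine, CPU-only engine; production-scale replication of the
  full phase diagrams is out of scope.
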