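# Methods

This note records the model implemented in `sepcm`, the numerical choices
behind it, and what the shipped benchmarks do and do not establish.

## Semi-empirical electronic structure

The electronic-structure core is a restricted closed-shell NDDO
(neglect of diatomic differential overlap) SCF over an s,p valence basis
for H, C, N and O, with the published MNDO (1977), AM1 (1985) and PM3
(1989) parameter sets embedded as JSON data files. Quantities derived from
the primary constants are recomputed at load time rather than stored:

* the multipole charge separations `D1 = <2s|z|2pz>` and
  `D2 = sqrt((2n+1)(2n+2)/20)/zeta_p`,
* the Klopman–Ohno radii `rho0`, `rho1`, `rho2` from the one-center limits
  `[q,q](0) = g_ss`, `[mu,mu](0) = h_sp` and `[Q,Q](0) = (g_pp - g_p2)/2`
  (Brent root solves on the explicit damped point-charge sums).

Two-center two-electron integrals use the classical point-multipole
representation of the one-center orbital-pair densities (monopole; ±1/2
dipole charges at ±D1; linear and square quadrupoles built from D2)
interacting through the Klopman–Ohno kernel
`1/sqrt(r² + (rho_l + rho_l')²)`, evaluated in a bond-aligned local frame
and rotated to the molecular frame by transforming the p functions as
vectors. The in-plane quadrupole integral `(pp'|pp')` is replaced by the
cylinder identity `[(pp|pp) - (pp|p'p')]/2`; without it the finite square
quadrupole breaks exact rotational invariance at the 1e-6 eV level.
Resonance terms are `beta_mu,nu = (beta_mu + beta_nu) S_mu,nu / 2` with
exact Slater-orbital overlaps evaluated in prolate-spheroidal coordinates
(generic polynomial assembly + A/B auxiliary functions; no hand-expanded
special cases). Core–core repulsion uses the MNDO exponential screening
(with the N–H/O–H distance-weighted variant) plus the AM1/PM3 Gaussian
corrections.

Unit conventions are the historical ones the parameterizations were fitted
with (1 hartree = 27.21 eV, 1 bohr = 0.529167 Å, 1 eV = 23.061 kcal/mol);
modern CODATA values shift heats of formation by a few hundredths of a
kcal/mol and break agreement with the published molecular values. The SCF
uses a charge-scaled atomic-occupation initial guess, DIIS (subspace 8,
error `FP - PF`), and converges on both the energy (1e-7 eV) and the
density (1e-6). Validation: optimized heats of formation for CH4, H2O,
NH3 and H2 reproduce the published MNDO/AM1/PM3 values to 0.1 kcal/mol,
which exercises every term above simultaneously.

## Cavity construction

The solute cavity is the union of atom-centered spheres (Bondi radii × 1.2
by default, both configurable — the radii are the dominant uncertainty when
comparing solvation energies across codes). Each sphere carries a pentakis-
dodecahedral mesh of 60 spherical triangles, subdivided to 240 or 960.
Exposed areas of triangles cut by neighbouring spheres are computed exactly
by clipping the spherical polygon against the intersection circles and
applying the Gauss–Bonnet theorem (great-circle arcs carry no geodesic
curvature; a small-circle arc of angular radius θ contributes cosθ·Δφ).
The clipped areas reproduce the analytic two-sphere union area to machine
precision at every separation and tessera count; rare degenerate topologies
(cap holes, multiply-split pieces) fall back to subdivision sampling.

Representative points are the normalized surface centroids
`∫x dA = ½∮ x × dl`, evaluated from the same boundary representation.
A plain vertex average is *not* used: it jumps when a near-tangent clip
inserts boundary vertices, and those jumps made PCM geometry optimizations
stall far from the threshold. A centroid that lands inside a neighbouring
sphere (concave crescents) is rotated back to the exposed side of the cap.

The mesh is seeded in a molecule-fixed frame built from smooth
index-weighted coordinate moments, so the tessellation is exactly
equivariant under rigid rotation (total area invariant to ~1e-14) while
remaining a continuous function of the coordinates — an argmax/principal-
axis frame would re-orient discontinuously under small distortions and
poison finite-difference cavity derivatives. Rebuilds at displaced
geometries reuse every sphere whose center and cap environment are
unchanged.

## C-PCM electrostatics

Apparent surface charges solve `D q = -f(ε) V` with
`D_ii = 1.0694·sqrt(4π/a_i)`, `D_ij = 1/|s_i - s_j|`, and
`f = (ε-1)/ε` (water ε = 78.39; `(ε-1)/(ε+0.5)` available). The solute
potential V at each tessera is the valence-core Coulomb term plus the
density-contracted basis–tessera interaction integrals: the same
point-multipole configurations as the two-electron integrals but with the
Klopman–Ohno radii set to zero (bare point charges), evaluated in the
atom→tessera local frame and rotated by direction cosines. Denominators
are floored at 0.1 bohr against pathological near-field geometries (never
active for tesserae on a sane cavity). The PCM Fock contribution is
`F_mu,nu = -Σ_i q_i <mu nu>_i`, rebuilt from the current density every SCF
iteration (fully coupled), and the interaction free energy `½ Σ q_i V_i`
enters the variational total energy.

Two numerical-robustness devices address the classic GEPOL seam pathology
(tesserae of neighbouring spheres nearly coinciding on the intersection
circle):

* off-diagonal couplings are saturated continuously at
  `0.8·sqrt(D_ii D_jj)` — inactive for regularly spaced tesserae;
* the direct solver works through an eigendecomposition whose spectrum is
  floored *smoothly* at 0.25 au
  (`w' = floor + [(w-floor) + sqrt((w-floor)² + floor²)]/2`). Healthy
  cavities have minimum eigenvalues well above 0.5, so the floor only
  removes near-null redundant charge modes, which otherwise act as
  spurious energy sinks that attract the geometry optimizer. A hard
  `max(w, floor)` was tried first and rejected: it leaves kinks on the
  energy surface exactly where optimizations land.

Cavities above 2500 tesserae (the 960-tesserae single points) use
Jacobi-preconditioned conjugate gradients warm-started across SCF
iterations instead; their spectra are well-conditioned and no floor is
applied, so the reported solvation energies are unregularized.

## Gradients

At SCF convergence the free energy is variational in the density, so the
total gradient splits into fixed-density partial derivatives:

1. **core term** — central differences (1e-3 bohr) of the gas-like energy
   expression, exploiting pairwise separability so each displacement
   re-evaluates only the pairs touching the moved atom (the one-center
   terms are geometry-independent);
2. **reaction-field potential term** — fully analytic `Σ q_i ∂V_i/∂x` at
   fixed tesserae: closed-form nuclear Coulomb derivatives plus the chain
   rule through the local-frame distance, the direction cosines and the
   four unique multipole integrals;
3. **cavity-geometric term** — finite differences (1e-4 bohr) of
   `-f/2·VᵀD⁻¹V` through the frozen-frame cavity rebuild, capturing tessera
   motion, exposed-area changes and the D-matrix dependence together.
   Stencils straddling a tessellation discontinuity (tessera count change)
   are detected; second-order one-sided stencils on the reference cavity's
   branch, displaced-pair estimates and step halving (up to three times)
   are tried in turn, and a persistent event is flagged rather than
   smoothed. Inside geometry optimization the term
   uses forward differences (half the rebuilds; O(h) bias ≪ the 5e-4
   convergence threshold); elsewhere central differences.

Only the numerical cavity-term mode is provided; an analytic Gauss–Bonnet
area-derivative mode was considered and dropped (the clipped-polygon areas
are piecewise-smooth compositions of many geometric primitives, and the
finite-difference route through the deterministic rebuild is unambiguous
and directly testable). The assembled gradient matches full central
finite differences of the total solvated energy to ~1e-7 au/bohr on
ammonium at 60 tesserae/sphere, and to < 1e-4 au/bohr across all twenty
benchmark cations.

## Optimization and frequencies

Cartesian BFGS with unit initial Hessian, per-component step cap 0.3 bohr,
backtracking acceptance, convergence on the maximum gradient component
(5e-4 au default), stall declaration after two consecutive failed
line searches (the best geometry is kept and usable). A flag freezes the
Hessian update, a standard workaround for
stalling small-cation optimizations on jagged PCM surfaces. Hessians are double differences of
gradients (0.01 bohr), symmetrized; frequencies come from the
mass-weighted, rigid-body-projected Hessian, with imaginary modes reported
as negative wavenumbers. The solvated-vs-gas frequency deviation statistic
pairs the two sorted spectra by index (no mode tracking) and excludes
imaginary modes, with counts reported.

## The benchmark workflow

Per cation: gas-phase optimization from the shipped fixture; PCM
re-optimization at 60 tesserae/sphere starting from the gas minimum (mesh
frame frozen at that geometry); 960-tesserae single point at the solvated
geometry. The reported magnitude is
`-[E_total^PCM(solv geom) - E_total^gas(gas geom)]`, positive for cations —
i.e. including solute electronic and geometric relaxation, which is the
standard operational meaning of an electrostatic solvation free energy in
this family of methods; the bare `½ q·V` of the final point is reported
alongside and differs by well under 1 kcal/mol for these cations.

Fixture geometries were generated once from the benchmark SMILES strings
(RDKit ETKDG + MMFF94, fixed seed) and ship as XYZ files; all results
follow geometry optimization, so only chemical sanity of the starting
points matters. SMILES processing is not a runtime dependency.

Problem sizes used by the shipped checks: the three-stage pipeline runs
for the full ammonium series A1–A10 plus O1, O3 and O8 (the three oxonium
species with machine-encoded reference values); the gradient/finite-
difference oracle runs over all twenty fixtures at their starting
geometries at 60 tesserae/sphere; the solver-equivalence check uses a
~6000-tessera cavity. The remaining oxonium species run through the same
code path and can be enabled with `sepcm study`.

## Known limitations

* Closed-shell RHF only; elements H, C, N, O only; no d functions.
* Electrostatics only — no cavitation or dispersion-repulsion terms.
* The GEPOL-with-Gauss-Bonnet surface is piecewise smooth in the nuclear
  coordinates; optimizations of the smallest cations can stall in kinked
  valleys (detected and flagged) - a known failure mode of
  this class of tessellation.
* Literature reference values for the cation set come from a D-PCM
  implementation with a different (unpublished) radii protocol; agreement
  beyond ~1–2 kcal/mol per molecule is not expected, and the mean signed
  deviation of the ammonium series (≈ −1.3 kcal/mol) is the sharper
  statistic.
* The smooth eigenvalue floor perturbs the lowest surface-charge mode of
  small-cavity solves by ≲0.1%; the production 960-tessera single points
  bypass it entirely.
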