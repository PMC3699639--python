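# sepcm

Semi-empirical NDDO electronic structure (MNDO, AM1, PM3) coupled to the
conductor-like polarizable continuum model (C-PCM) of solvation, for
molecules built from H, C, N and O.

`sepcm` is for people who want a small, transparent, fully self-contained
implementation of implicit solvation on top of the classical semi-empirical
methods: computational chemists studying continuum-solvation numerics
(cavity discretization, surface-charge conditioning, PCM gradients), and
anyone needing fast solvation free energies and solvated geometries of
small organic ions without a large quantum-chemistry stack.

## The model

The solute is treated with a restricted closed-shell NDDO SCF (the
published MNDO/AM1/PM3 parameter sets are embedded). The solvent is a
dielectric continuum: the solute sits in a cavity of interlocked
atom-centered spheres whose surface is divided into tesserae (GEPOL
meshes, 60/240/960 per sphere, exposed areas by the Gauss–Bonnet theorem).
Apparent surface charges q on the tesserae solve

    D q = -f(ε) V,      f(ε) = (ε - 1)/ε,

where `D_ii = 1.0694 √(4π/a_i)`, `D_ij = 1/|s_i - s_j|`, and `V_i` is the
solute electrostatic potential at tessera i — valence cores plus the NDDO
density contracted with point-multipole interaction integrals `<μν>_i`.
The charges feed back into the Fock matrix, `F^PCM_μν = -Σ_i q_i <μν>_i`,
and the electrostatic interaction free energy is `ΔG_el = ½ Σ_i q_i V_i`.
Geometry optimization uses an assembled gradient: a numerical core
semi-empirical term, the analytic `Σ q_i ∂V_i/∂x` reaction-field term, and
a numerical cavity-geometric term. Harmonic frequencies come from
double-difference Hessians. See `docs/methods.md` for the complete
description and numerical choices.

## Worked example

Solvation free energy of the ammonium cation in water (PM3, Bondi radii
× 1.2, gas-phase optimization, C-PCM re-optimization at 60
tesserae/sphere, 960-tessera single point):

```
$ sepcm solvate A1.xyz            # ammonium fixture, charge=1 in the file
gas optimization:   3 steps, converged=True
PCM optimization:   1 steps, converged=True, stalled=False
E(gas, gas geom):   -7.98205520 hartree
E(PCM, solv geom):  -8.11151931 hartree
interaction dG_el:  -81.37 kcal/mol (0.5 q.V)
solvation magnitude: 81.24 kcal/mol
sum of ASCs:        -0.9827 (expected -0.9872)
```

The *solvation magnitude* is the total-energy drop on transfer from
vacuum to water, `-[E^PCM(solvated geometry) - E^gas(gas geometry)]`,
reported positive for cations — here 81.2 kcal/mol, with the bare
surface-charge interaction energy (−81.4 kcal/mol) shown alongside. The
sum of the induced surface charges obeys Gauss's law for a conductor-like
model, `Σq ≈ -f(ε)·(net charge) = -0.987`, to about half a percent of
discretization error.

The same library calls are available in Python:

```python
from sepcm import load_parameters, solvated_scf
from sepcm.pipeline import load_fixture

state = solvated_scf(load_fixture("A1"), load_parameters("PM3"), n_per_sphere=960)
print(state.pcm.dg_el_kcal)   # 0.5 q.V in kcal/mol
```

Other command-line verbs: `sepcm energy` (gas single point), `sepcm opt`
(gas or solvated geometry optimization), `sepcm freq` (harmonic
frequencies and the solvated-vs-gas deviation statistic), and
`sepcm study` (the full twenty-cation benchmark with per-molecule
deviations and series averages, written as JSON/CSV/markdown).

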