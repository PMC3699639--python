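"""Gradients of the total energy in the C-PCM reaction field.

At SCF convergence the free energy G = E_SE(P; x) + 0.5 q.V(P; x) is
variational in the density P, so dG/dx splits into partial derivatives at
fixed P:

1. core term      dE_SE/dx|_P   — central finite differences of the
   semi-empirical energy expression rebuilt from the integrals at the
   displaced geometry with the converged density held fixed;
2. reaction-field potential term  q . dV/dx|_cavity — fully analytic:
   derivatives of the nuclear Coulomb potential and of the rotated
   point-multipole interaction integrals with the tesserae held fixed;
3. cavity-geometric term — the dependence of G_pcm = -f/2 V.D^-1.V on the
   tessera positions and exposed areas (both V and D), evaluated by central
   differences through the deterministic cavity rebuild with the mesh frame
   frozen.  Tessellation discontinuities (a tessera appearing or vanishing
   inside the stencil) are detected, the step is halved up to three times,
   and a persistent discontinuity is flagged rather than smoothed.

Gradients are returned in hartree/bohr (au).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cavity import Cavity, cavity_displacement_rebuild
from .cpcm import (
    build_cpcm_matrix,
    electronic_potential,
    nuclear_potential,
    solute_integral_blocks,
    NEAR_FIELD_CLAMP,
)
from .molecule import Molecule
from .nddo import Basis, SCFError, SCFState
from .parameters import ParameterSet
from .units import EV

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# analytic derivatives of the tessera interaction integrals


def _multipole_scalar_derivatives(par, r):
    """d/dr of the four local-frame potentials; clamped branches get slope 0."""
    clamp = NEAR_FIELD_CLAMP

    def dinv(x):
        return np.where(x > clamp, -1.0 / np.maximum(x, clamp) ** 2, 0.0)

    dv_ss = dinv(r)
    if par.n_orbitals == 1:
        return dv_ss, None, None, None
    d1, d2 = par.d1, par.d2
    dv_sp = 0.5 * (dinv(r - d1) - dinv(r + d1))
    dv_sig = 0.5 * dinv(r) + 0.25 * (dinv(r - 2 * d2) + dinv(r + 2 * d2))
    rr = r * r + 4 * d2 * d2
    dv_pi = 0.5 * dinv(r) - 0.5 * r * rr ** (-1.5)
    return dv_ss, dv_sp, dv_sig, dv_pi


def tessera_integral_block_derivatives(par, rvecs: np.ndarray) -> np.ndarray:
    """d<mu nu>_i / dR_A as an (n_tess, 3, n_orb, n_orb) array (au/bohr).

    rvecs = s_i - R_A; derivatives are with respect to the atom position
    R_A at fixed tessera positions (hence the overall minus sign on the
    rvec derivatives).
    """
    from .cpcm import _multipole_scalars

    r = np.linalg.norm(rvecs, axis=1)
    e = rvecs / r[:, None]
    n = par.n_orbitals
    nt = len(r)
    v_ss, v_sp, v_sig, v_pi = _multipole_scalars(par, r)
    dv_ss, dv_sp, dv_sig, dv_pi = _multipole_scalar_derivatives(par, r)
    # de_j/drvec_k = (delta_jk - e_j e_k)/r
    eye = np.eye(3)
    de = (eye[None, :, :] - np.einsum("tj,tk->tjk", e, e)) / r[:, None, None]
    out = np.zeros((nt, 3, n, n))
    out[:, :, 0, 0] = dv_ss[:, None] * e
    if n > 1:
        # d(e_j Vsp)/drvec_k = de_jk Vsp + e_j Vsp' e_k
        dsp = de * v_sp[:, None, None] + np.einsum("tj,t,tk->tjk", e, dv_sp, e)
        out[:, :, 0, 1:] = dsp.transpose(0, 2, 1)
        out[:, :, 1:, 0] = out[:, :, 0, 1:]
        dvdiff = v_sig - v_pi
        ddvdiff = dv_sig - dv_pi
        term1 = np.einsum("tjk,tl,t->tkjl", de, e, dvdiff)
        term2 = np.einsum("tj,tlk,t->tkjl", e, de, dvdiff)
        term3 = np.einsum("tj,tl,t,tk->tkjl", e, e, ddvdiff, e)
        term4 = np.einsum("jl,t,tk->tkjl", eye, dv_pi, e)
        out[:, :, 1:, 1:] = term1 + term2 + term3 + term4
    return -out  # d/dR_A = -d/d(rvec)


def potential_derivative(
    mol: Molecule,
    params: ParameterSet,
    cavity: Cavity,
    density: np.ndarray,
    atom_index: int | None = None,
) -> np.ndarray:
    """Analytic dV_i/dR_A at fixed tessera positions (au/bohr).

    Returns (natoms, 3, n_tess), or (3, n_tess) for a single atom.  Includes
    the nuclear Coulomb term and the density-contracted derivative of the
    interaction integrals.
    """
    basis = Basis(mol, params)
    atoms = range(mol.natoms) if atom_index is None else [atom_index]
    out = np.zeros((len(list(atoms)), 3, cavity.n_tesserae))
    atoms = range(mol.natoms) if atom_index is None else [atom_index]
    for ia, a in enumerate(atoms):
        par = basis.atom_params[a]
        rvecs = cavity.positions - mol.coords[a][None, :]
        r = np.linalg.norm(rvecs, axis=1)
        # nuclear: d(Z_A/r)/dR_A = +Z_A (s - R_A)/r^3
        out[ia] = (par.zval * rvecs / r[:, None] ** 3).T
        # electronic: dV_el/dR_A = -sum_{mu nu in A} P_mu,nu dM/dR_A
        dblocks = tessera_integral_block_derivatives(par, rvecs)
        sl = basis.atom_slice(a)
        pblock = density[sl, sl]
        out[ia] -= np.einsum("tkij,ij->kt", dblocks, pblock)
    return out[0] if atom_index is not None else out


def electronic_potential_derivative(
    density: np.ndarray,
    mol: Molecule,
    params: ParameterSet,
    cavity: Cavity,
    atom_index: int,
) -> np.ndarray:
    """Analytic dV^el_i/dR_A at fixed density and tessera positions,
    (3, n_tess) in au/bohr: the chain rule through the local-frame distance
    and direction cosines of the rotated multipole integrals."""
    basis = Basis(mol, params)
    par = basis.atom_params[atom_index]
    rvecs = cavity.positions - mol.coords[atom_index][None, :]
    dblocks = tessera_integral_block_derivatives(par, rvecs)
    sl = basis.atom_slice(atom_index)
    return -np.einsum("tkij,ij->kt", dblocks, density[sl, sl])


def nuclear_potential_derivative(
    mol: Molecule,
    params: ParameterSet,
    cavity: Cavity,
    atom_index: int,
    include_tessera_motion: bool = False,
) -> np.ndarray:
    """Analytic dV^nuc_i/dR_A, (3, n_tess) in au/bohr.

    With ``include_tessera_motion`` the tesserae on atom A's sphere are
    taken to translate rigidly with the atom (exact for uncut tesserae; cut
    tesserae additionally deform, which the numerical cavity-geometric
    gradient term accounts for).
    """
    z = np.array([params[s].zval for s in mol.symbols], dtype=float)
    rvecs = cavity.positions - mol.coords[atom_index][None, :]
    r = np.linalg.norm(rvecs, axis=1)
    out = (z[atom_index] * rvecs / r[:, None] ** 3).T
    if include_tessera_motion:
        parent = np.array(
            [cavity.spheres[i].atom_index for i in cavity.sphere_index]
        )
        riding = np.where(parent == atom_index)[0]
        for i in riding:
            dvds = np.zeros(3)
            for b in range(mol.natoms):
                rv = cavity.positions[i] - mol.coords[b]
                dvds -= z[b] * rv / np.linalg.norm(rv) ** 3
            out[:, i] -= dvds  # ds_i/dR_A = identity for riding tesserae
    return out


# ---------------------------------------------------------------------------
# numerical cavity-geometric term


@dataclass
class GradientReport:
    """Total gradient with a term-by-term decomposition (au/bohr)."""

    total: np.ndarray  # (natoms, 3)
    core: np.ndarray
    potential_term: np.ndarray
    cavity_term: np.ndarray
    discontinuities: list = field(default_factory=list)

    def dump(self, path, symbols=None) -> None:
        with open(path, "w") as fh:
            fh.write("# atom axis total core q.dV/dx cavity (hartree/bohr)\n")
            for a in range(len(self.total)):
                sym = symbols[a] if symbols else str(a)
                for k, ax in enumerate("xyz"):
                    fh.write(
                        f"{sym:4s} {ax} {self.total[a, k]: .10e} {self.core[a, k]: .10e} "
                        f"{self.potential_term[a, k]: .10e} {self.cavity_term[a, k]: .10e}\n"
                    )


def _pcm_geometric_energy(
    mol: Molecule,
    params: ParameterSet,
    cavity: Cavity,
    density: np.ndarray,
    f: float,
    diagonal_constant: float,
    q_warm: np.ndarray | None = None,
) -> float:
    """G_pcm = 0.5 q.V (hartree) for given cavity with solute sources fixed.

    Uses the same floored-eigenvalue solve as the SCF path so that the
    finite-difference stencil samples exactly the energy surface the SCF
    defines.
    """
    from .cpcm import floored_eigendecomposition, floored_solve

    v = nuclear_potential(mol, cavity, params) + electronic_potential(
        density, solute_integral_blocks(mol, params, cavity.positions)
    )
    d = build_cpcm_matrix(cavity, diagonal_constant)
    q = floored_solve(floored_eigendecomposition(d), -f * v)
    return 0.5 * float(q @ v)


def cavity_term_gradient(
    mol: Molecule,
    params: ParameterSet,
    cavity: Cavity,
    density: np.ndarray,
    f: float,
    step: float = 1e-4,
    diagonal_constant: float = 1.0694,
    mode: str = "numerical",
    scheme: str = "central",
    q_ref: np.ndarray | None = None,
):
    """Cavity-geometric contribution to dG/dx (au/bohr) by finite
    differences of G_pcm through the frozen-frame cavity rebuild.

    ``scheme="central"`` is the accurate default; ``"forward"`` halves the
    rebuild count (the O(h) bias at step 1e-4 bohr sits well below the
    optimizer threshold) and is used inside geometry optimization.
    Returns (gradient, discontinuity_flags).
    """
    if mode != "numerical":
        raise NotImplementedError(
            "only the numerical cavity-term mode is provided; see docs/methods.md"
        )
    n_ref = cavity.n_tesserae
    g_ref = None
    if scheme != "central":
        g_ref = _pcm_geometric_energy(
            mol, params, cavity, density, f, diagonal_constant, q_warm=q_ref
        )
    grad = np.zeros((mol.natoms, 3))
    flags = []

    def _eval(a, k, sgn, h):
        x = mol.coords.copy()
        x[a, k] += sgn * h
        cav = cavity_displacement_rebuild(cavity, mol.with_coords(x))
        g = _pcm_geometric_energy(
            mol, params, cav, density, f, diagonal_constant, q_warm=q_ref
        )
        return g, cav.n_tesserae

    if scheme == "central" and g_ref is None:
        g_ref = _pcm_geometric_energy(
            mol, params, cavity, density, f, diagonal_constant, q_warm=q_ref
        )

    def _one_sided(a, k, sgn, h):
        """Second-order one-sided stencil on the reference branch, or None."""
        g1, c1 = _eval(a, k, sgn, h)
        if c1 != n_ref:
            return None
        g2, c2 = _eval(a, k, sgn, 2.0 * h)
        if c2 != n_ref:
            return None
        return sgn * (-3.0 * g_ref + 4.0 * g1 - g2) / (2.0 * h)

    for a in range(mol.natoms):
        for k in range(3):
            h = step
            val = None
            flagged = False
            for attempt in range(4):
                if scheme == "central":
                    gp, cp = _eval(a, k, 1.0, h)
                    gm, cm = _eval(a, k, -1.0, h)
                    if cp == cm == n_ref:
                        val = (gp - gm) / (2.0 * h)
                        break
                    # event inside the stencil: one-sided on the branch the
                    # reference cavity belongs to, second order
                    flagged = True
                    val = _one_sided(a, k, 1.0, h)
                    if val is None:
                        val = _one_sided(a, k, -1.0, h)
                    if val is not None:
                        break
                    if cp == cm:  # both sides on the same (other) branch
                        val = (gp - gm) / (2.0 * h)
                        break
                else:
                    gp, cp = _eval(a, k, 1.0, h)
                    if cp == n_ref:
                        val = (gp - g_ref) / h
                        break
                    flagged = True
                    val = _one_sided(a, k, -1.0, h)
                    if val is not None:
                        break
                    gm, cm = _eval(a, k, -1.0, h)
                    if cp == cm:
                        val = (gp - gm) / (2.0 * h)
                        break
                h *= 0.5
            if val is None:  # give the least-biased estimate available
                val = (gp - gm) / (2.0 * h)
                flagged = True
            if flagged:
                flags.append((a, k))
                logger.info(
                    "tessellation discontinuity in cavity gradient stencil at atom %d axis %d",
                    a,
                    k,
                )
            grad[a, k] = val
    return grad, flags


# ---------------------------------------------------------------------------
# assembled gradients


def core_gradient_fixed_density(
    mol: Molecule, params: ParameterSet, density: np.ndarray, step: float = 1e-3
) -> np.ndarray:
    """dE_SE/dx at fixed density by central differences (au/bohr).

    Valid as the SCF-relaxed gas-phase gradient by the variational theorem.
    Uses the pairwise decomposition of the fixed-density energy, so each
    displacement re-evaluates only the pairs touching the moved atom.
    """
    from .nddo import core_gradient_pairwise

    return core_gradient_pairwise(mol, params, density, step) / EV


def gas_gradient(
    mol: Molecule, params: ParameterSet, state: SCFState | None = None, step: float = 1e-3
) -> np.ndarray:
    """Gas-phase total-energy gradient (au/bohr)."""
    from .nddo import scf

    if state is None:
        state = scf(mol, params)
        if not state.converged:
            raise SCFError("gas-phase SCF did not converge at the gradient geometry")
    return core_gradient_fixed_density(mol, params, state.density, step)


def total_gradient(
    mol: Molecule,
    params: ParameterSet,
    state: SCFState,
    core_step: float = 1e-3,
    cavity_step: float = 1e-4,
    cavity_scheme: str = "central",
) -> GradientReport:
    """Assembled total gradient at a converged (PCM-)SCF state (au/bohr)."""
    core = core_gradient_fixed_density(mol, params, state.density, core_step)
    natoms = mol.natoms
    if state.pcm is None:
        zero = np.zeros((natoms, 3))
        return GradientReport(total=core, core=core, potential_term=zero, cavity_term=zero)
    att = state.pcm
    cavity = att.cavity
    q = att.charges
    dv = potential_derivative(mol, params, cavity, state.density)
    pot_term = np.einsum("t,akt->ak", q, dv)
    cav_term, flags = cavity_term_gradient(
        mol,
        params,
        cavity,
        state.density,
        att.f,
        cavity_step,
        scheme=cavity_scheme,
        q_ref=q,
    )
    return GradientReport(
        total=core + pot_term + cav_term,
        core=core,
        potential_term=pot_term,
        cavity_term=cav_term,
        discontinuities=flags,
    )
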