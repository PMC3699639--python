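"""Gas-phase NDDO electronic structure: core Hamiltonian, Fock build,
restricted closed-shell SCF with DIIS, heat of formation, numerical gradient.

Energies are carried in eV throughout (the native unit of the MNDO-family
parameterizations); heats of formation are reported in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecule import GeometryError, Molecule
from .multipole import local_repulsion_block, one_center_repulsion, two_center_repulsion
from .overlap import diatomic_overlap
from .parameters import ParameterSet
from .units import BOHR_TO_ANGSTROM, EVKCAL


class SCFError(RuntimeError):
    pass


@dataclass
class SCFState:
    """Converged (or best-effort) self-consistent-field result."""

    density: np.ndarray
    fock: np.ndarray
    orbital_energies: np.ndarray
    mo_coefficients: np.ndarray
    electronic_energy: float  # eV, 0.5 * sum P (H + F_gas)
    core_repulsion_energy: float  # eV
    pcm_energy: float  # eV, 0.5 * q.V (0 in gas phase)
    total_energy: float  # eV, electronic + core + pcm
    heat_of_formation: float  # kcal/mol
    converged: bool
    iterations: int
    pcm: object = None  # solvent-model attachment (set by the C-PCM hook)


class Basis:
    """Orbital bookkeeping for one molecule: atom offsets and parameters."""

    def __init__(self, mol: Molecule, params: ParameterSet):
        self.mol = mol
        self.params = params
        self.atom_params = [params[s] for s in mol.symbols]
        self.offsets = []
        n = 0
        for p in self.atom_params:
            self.offsets.append(n)
            n += p.n_orbitals
        self.n_orbitals = n
        self.n_electrons = sum(p.zval for p in self.atom_params) - mol.charge
        if self.n_electrons <= 0 or self.n_electrons % 2 != 0:
            raise GeometryError(
                f"closed-shell SCF needs a positive even electron count, got {self.n_electrons}"
            )

    def atom_slice(self, i: int) -> slice:
        return slice(self.offsets[i], self.offsets[i] + self.atom_params[i].n_orbitals)


class ElectronicStructure:
    """All geometry-dependent integrals for one molecule, plus energy/Fock
    evaluation at a given density.

    Building this object is the expensive step; evaluating the Fock matrix
    or the fixed-density energy afterwards is cheap.  That split is what the
    numerical gradients exploit.
    """

    def __init__(self, mol: Molecule, params: ParameterSet):
        self.basis = Basis(mol, params)
        self.mol = mol
        self.params = params
        nb = self.basis.n_orbitals
        dm = mol.distance_matrix()
        n = mol.natoms
        if n > 1 and np.min(dm[np.triu_indices(n, 1)]) * BOHR_TO_ANGSTROM < 1e-3:
            raise GeometryError("overlapping nuclei (interatomic distance < 1e-3 angstrom)")

        ap = self.basis.atom_params
        self.pair_g = {}  # (i, j) i<j -> (ni, ni, nj, nj) eV
        hcore = np.zeros((nb, nb))
        e_core = 0.0
        for i in range(n):
            si = self.basis.atom_slice(i)
            pi = ap[i]
            hcore[si, si] += np.diag(
                [pi.uss] + [pi.upp] * 3 if pi.n_orbitals == 4 else [pi.uss]
            )
        for i in range(n):
            pi = ap[i]
            si = self.basis.atom_slice(i)
            for j in range(i + 1, n):
                pj = ap[j]
                sj = self.basis.atom_slice(j)
                rvec = mol.coords[j] - mol.coords[i]
                g = two_center_repulsion(pi, pj, rvec)
                self.pair_g[(i, j)] = g
                # core-electron attraction: (mu nu | s_B s_B) with core charge
                hcore[si, si] += -pj.zval * g[:, :, 0, 0]
                hcore[sj, sj] += -pi.zval * g[0, 0, :, :]
                # resonance
                s = diatomic_overlap(pi, pj, rvec)
                beta_i = np.array(
                    [pi.beta_s] + [pi.beta_p] * 3 if pi.n_orbitals == 4 else [pi.beta_s]
                )
                beta_j = np.array(
                    [pj.beta_s] + [pj.beta_p] * 3 if pj.n_orbitals == 4 else [pj.beta_s]
                )
                hb = 0.5 * (beta_i[:, None] + beta_j[None, :]) * s
                hcore[si, sj] += hb
                hcore[sj, si] += hb.T
                e_core += _pair_core_repulsion(pi, pj, float(dm[i, j]), params.method)
        self.hcore = hcore
        self.core_repulsion = e_core
        self.one_center = [one_center_repulsion(p) for p in ap]

    def fock(self, density: np.ndarray) -> np.ndarray:
        """Gas-phase Fock matrix at a given closed-shell density (eV)."""
        b = self.basis
        f = self.hcore.copy()
        for i, g in enumerate(self.one_center):
            si = b.atom_slice(i)
            pblock = density[si, si]
            f[si, si] += np.einsum("ls,ijls->ij", pblock, g) - 0.5 * np.einsum(
                "ls,iljs->ij", pblock, g
            )
        for (i, j), g in self.pair_g.items():
            si, sj = b.atom_slice(i), b.atom_slice(j)
            pii = density[si, si]
            pjj = density[sj, sj]
            pij = density[si, sj]
            f[si, si] += np.einsum("ls,ijls->ij", pjj, g)
            f[sj, sj] += np.einsum("ij,ijls->ls", pii, g)
            f[si, sj] += -0.5 * np.einsum("js,ijls->il", pij, g)
            f[sj, si] = f[si, sj].T
        return f

    def energy(self, density: np.ndarray, fock: np.ndarray | None = None) -> float:
        """Total gas-phase energy (eV) at fixed density (electronic + core)."""
        if fock is None:
            fock = self.fock(density)
        e_el = 0.5 * float(np.sum(density * (self.hcore + fock)))
        return e_el + self.core_repulsion


def _pair_core_repulsion(pi, pj, r_bohr: float, method: str) -> float:
    """Pairwise core-core repulsion in eV (MNDO screening; AM1/PM3 add
    Gaussian corrections).  Distances in the screening terms are in
    angstrom, matching the published alpha and Gaussian parameters."""
    r_ang = r_bohr * BOHR_TO_ANGSTROM
    gss = local_repulsion_block(pi, pj, r_bohr)[0, 0]  # eV
    zz = pi.zval * pj.zval
    pair = {pi.symbol, pj.symbol}
    if pair == {"N", "H"} or pair == {"O", "H"}:
        heavy, light = (pi, pj) if pi.symbol != "H" else (pj, pi)
        scale = 1.0 + r_ang * np.exp(-heavy.alpha * r_ang) + np.exp(-light.alpha * r_ang)
    else:
        scale = 1.0 + np.exp(-pi.alpha * r_ang) + np.exp(-pj.alpha * r_ang)
    e = zz * gss * scale
    if method in ("AM1", "PM3"):
        gauss = 0.0
        for k, l, m in pi.gaussian_terms:
            gauss += k * np.exp(-l * (r_ang - m) ** 2)
        for k, l, m in pj.gaussian_terms:
            gauss += k * np.exp(-l * (r_ang - m) ** 2)
        e += zz / r_ang * gauss
    return float(e)


def _beta_vector(par) -> np.ndarray:
    if par.n_orbitals == 1:
        return np.array([par.beta_s])
    return np.array([par.beta_s, par.beta_p, par.beta_p, par.beta_p])


def pair_interaction_energy(
    pi, pj, rvec, p_ii, p_jj, p_ij, method: str
) -> float:
    """All geometry-dependent energy terms of one atom pair at fixed density
    (eV): core attraction, resonance, two-center two-electron Coulomb and
    exchange, and core-core repulsion.

    The fixed-density total energy is the sum of these over pairs plus a
    geometry-independent one-center part, so finite-difference gradients
    need only re-evaluate the pairs touching the displaced atom.
    """
    g = two_center_repulsion(pi, pj, rvec)
    e = -pj.zval * float(np.sum(p_ii * g[:, :, 0, 0]))
    e += -pi.zval * float(np.sum(p_jj * g[0, 0, :, :]))
    s = diatomic_overlap(pi, pj, rvec)
    bi, bj = _beta_vector(pi), _beta_vector(pj)
    e += 2.0 * float(np.sum(p_ij * (0.5 * (bi[:, None] + bj[None, :]) * s)))
    e += float(np.einsum("ij,ijkl,kl->", p_ii, g, p_jj))
    e -= 0.5 * float(np.einsum("ml,ns,mnls->", p_ij, p_ij, g))
    e += _pair_core_repulsion(pi, pj, float(np.linalg.norm(rvec)), method)
    return e


def core_gradient_pairwise(
    mol: Molecule, params: ParameterSet, density: np.ndarray, step: float = 1e-3
) -> np.ndarray:
    """Central-difference dE_SE/dx at fixed density (eV/bohr), exploiting
    pairwise separability: only pairs touching the displaced atom are
    re-evaluated."""
    basis = Basis(mol, params)
    ap = basis.atom_params
    n = mol.natoms
    grad = np.zeros((n, 3))
    slices = [basis.atom_slice(i) for i in range(n)]
    for a in range(n):
        pa = ap[a]
        sa = slices[a]
        p_aa = density[sa, sa]
        for k in range(3):
            vals = []
            for sgn in (1.0, -1.0):
                xa = mol.coords[a].copy()
                xa[k] += sgn * step
                e = 0.0
                for j in range(n):
                    if j == a:
                        continue
                    e += pair_interaction_energy(
                        pa,
                        ap[j],
                        mol.coords[j] - xa,
                        p_aa,
                        density[slices[j], slices[j]],
                        density[sa, slices[j]],
                        params.method,
                    )
                vals.append(e)
            grad[a, k] = (vals[0] - vals[1]) / (2.0 * step)
    return grad


def core_core_repulsion(mol: Molecule, params: ParameterSet) -> float:
    """Total core-core repulsion energy (eV)."""
    e = 0.0
    dm = mol.distance_matrix()
    ap = [params[s] for s in mol.symbols]
    for i in range(mol.natoms):
        for j in range(i + 1, mol.natoms):
            e += _pair_core_repulsion(ap[i], ap[j], float(dm[i, j]), params.method)
    return e


def build_core_hamiltonian(mol: Molecule, params: ParameterSet) -> np.ndarray:
    """One-electron (core) Hamiltonian matrix in eV."""
    return ElectronicStructure(mol, params).hcore


def initial_density(basis: Basis) -> np.ndarray:
    occ = []
    for p in basis.atom_params:
        occ.extend(p.valence_occupations)
    occ = np.array(occ)
    occ *= basis.n_electrons / occ.sum()
    return np.diag(occ)


@dataclass
class SCFOptions:
    max_iter: int = 200
    energy_tol: float = 1e-7  # eV
    density_tol: float = 1e-6
    diis: bool = True
    diis_size: int = 8


def scf(
    mol: Molecule,
    params: ParameterSet,
    options: SCFOptions | None = None,
    pcm_hook=None,
    es: ElectronicStructure | None = None,
    p0: np.ndarray | None = None,
) -> SCFState:
    """Restricted closed-shell SCF.

    ``pcm_hook(P) -> (F_pcm_eV, e_pcm_eV, attachment)`` is rebuilt from the
    current density every iteration; the returned total energy then includes
    the solute-solvent interaction free energy e_pcm = 0.5 q.V.
    Non-convergence is reported on the returned state, not raised.
    """
    options = options or SCFOptions()
    if es is None:
        es = ElectronicStructure(mol, params)
    basis = es.basis
    nocc = basis.n_electrons // 2
    p = initial_density(basis) if p0 is None else p0.copy()

    fock_hist, err_hist = [], []
    e_old = None
    converged = False
    niter = 0
    e_pcm = 0.0
    attachment = None
    f = es.hcore
    for niter in range(1, options.max_iter + 1):
        f_gas = es.fock(p)
        if pcm_hook is not None:
            f_pcm, e_pcm, attachment = pcm_hook(p)
            f = f_gas + f_pcm
        else:
            f = f_gas
        e_total = 0.5 * float(np.sum(p * (es.hcore + f_gas))) + es.core_repulsion + e_pcm

        if options.diis:
            err = f @ p - p @ f
            fock_hist.append(f)
            err_hist.append(err)
            if len(fock_hist) > options.diis_size:
                fock_hist.pop(0)
                err_hist.pop(0)
            if len(fock_hist) > 1:
                f = _diis_extrapolate(fock_hist, err_hist)

        eps, c = np.linalg.eigh(f)
        cocc = c[:, :nocc]
        p_new = 2.0 * cocc @ cocc.T
        dp = float(np.max(np.abs(p_new - p)))
        de = abs(e_total - e_old) if e_old is not None else np.inf
        p = p_new
        e_old = e_total
        if de < options.energy_tol and dp < options.density_tol:
            converged = True
            break

    # final consistent quantities at the converged density
    f_gas = es.fock(p)
    if pcm_hook is not None:
        f_pcm, e_pcm, attachment = pcm_hook(p)
        f = f_gas + f_pcm
    else:
        f = f_gas
    eps, c = np.linalg.eigh(f)
    e_el = 0.5 * float(np.sum(p * (es.hcore + f_gas)))
    e_total = e_el + es.core_repulsion + e_pcm
    hof = _heat_of_formation(e_total, basis)
    return SCFState(
        density=p,
        fock=f,
        orbital_energies=eps,
        mo_coefficients=c,
        electronic_energy=e_el,
        core_repulsion_energy=es.core_repulsion,
        pcm_energy=e_pcm,
        total_energy=e_total,
        heat_of_formation=hof,
        converged=converged,
        iterations=niter,
        pcm=attachment,
    )


def _diis_extrapolate(focks, errs):
    m = len(focks)
    b = -np.ones((m + 1, m + 1))
    b[m, m] = 0.0
    for i in range(m):
        for j in range(i, m):
            b[i, j] = b[j, i] = float(np.sum(errs[i] * errs[j]))
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        coeff = np.linalg.solve(b, rhs)[:m]
    except np.linalg.LinAlgError:
        return focks[-1]
    return sum(ci * fi for ci, fi in zip(coeff, focks))


def _heat_of_formation(e_total_ev: float, basis: Basis) -> float:
    eisol = sum(p.eisol for p in basis.atom_params)
    eheat = sum(p.eheat for p in basis.atom_params)
    return (e_total_ev - eisol) * EVKCAL + eheat


def heat_of_formation(state: SCFState, mol: Molecule, params: ParameterSet) -> float:
    """Standard NDDO heat of formation (kcal/mol) from a converged SCF state."""
    if not state.converged:
        raise SCFError("heat of formation requested from an unconverged SCF state")
    return _heat_of_formation(state.total_energy, Basis(mol, params))


def numerical_gradient(energy_fn, mol: Molecule, step: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of ``energy_fn(mol) -> eV`` in eV/bohr.

    One displacement pair per Cartesian component; raises a labelled error if
    the energy evaluation fails at a displaced geometry.
    """
    grad = np.zeros((mol.natoms, 3))
    x0 = mol.coords
    for a in range(mol.natoms):
        for k in range(3):
            vals = []
            for sgn in (1.0, -1.0):
                x = x0.copy()
                x[a, k] += sgn * step
                try:
                    vals.append(energy_fn(mol.with_coords(x)))
                except Exception as exc:
                    raise SCFError(
                        f"energy evaluation failed at displacement atom {a} axis {k} sign {sgn:+.0f}"
                    ) from exc
            grad[a, k] = (vals[0] - vals[1]) / (2.0 * step)
    return grad


def gas_phase_energy(mol: Molecule, params: ParameterSet, options=None) -> float:
    """Convenience: converged gas-phase total energy in eV."""
    state = scf(mol, params, options)
    if not state.converged:
        raise SCFError("gas-phase SCF did not converge")
    return state.total_energy
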