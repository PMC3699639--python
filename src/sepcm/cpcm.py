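"""Conductor-like PCM electrostatics over a tessellated cavity.

The apparent surface charges (ASCs) q on the cavity tesserae solve

    D q = -f(eps) V,

where D has diagonal k*sqrt(4*pi/a_i) and off-diagonal 1/|s_i - s_j| (au),
V is the solute electrostatic potential at the tesserae (nuclear cores plus
NDDO electronic density), and f(eps) = (eps-1)/eps scales the perfect-
conductor response to a finite dielectric.  The solute-solvent interaction
free energy is 0.5 * q.V, and the density dependence of V yields a
one-electron Fock contribution F^PCM_mu,nu = -sum_i q_i <mu nu>_i.

The basis-tessera interaction integrals <mu nu>_i use the NDDO point-
multipole representation of the one-center densities (monopole, dipole with
separation D1, linear/square quadrupoles with separation D2) with the
Klopman-Ohno damping radii set to zero, i.e. bare point charges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import LinearOperator, cg

from .cavity import Cavity
from .molecule import Molecule
from .nddo import Basis
from .parameters import ParameterSet
from .units import EV, EVKCAL

logger = logging.getLogger(__name__)

DIAGONAL_CONSTANT = 1.0694  # k in D_ii = k * sqrt(4 pi / a_i)
NEAR_FIELD_CLAMP = 0.1  # bohr floor on multipole denominators


class CpcmError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolventModel:
    """Dielectric continuum descriptor.

    f_form selects the conductor-scaling function: "eps" for (eps-1)/eps
    (default) or "eps+0.5" for (eps-1)/(eps+0.5).
    """

    epsilon: float = 78.39
    f_form: str = "eps"

    def __post_init__(self):
        if self.epsilon < 1.0:
            raise ValueError("relative permittivity must be >= 1")
        if self.f_form not in ("eps", "eps+0.5"):
            raise ValueError(f"unknown dielectric scaling form {self.f_form!r}")


WATER = SolventModel(78.39)


def dielectric_scale(solvent: SolventModel) -> float:
    eps = solvent.epsilon
    if solvent.f_form == "eps":
        return (eps - 1.0) / eps
    return (eps - 1.0) / (eps + 0.5)


OFFDIAGONAL_SATURATION = 0.80  # cap D_ij at this fraction of sqrt(D_ii D_jj)


def build_cpcm_matrix(cavity: Cavity, diagonal_constant: float = DIAGONAL_CONSTANT) -> np.ndarray:
    """Dense symmetric C-PCM matrix D (au) over the cavity tesserae.

    Off-diagonal couplings 1/|s_i - s_j| between tesserae that sit closer
    than their size warrants (seam tesserae of intersecting spheres) are
    saturated continuously at 0.8*sqrt(D_ii D_jj); this keeps the matrix
    safely positive definite for interlocked-sphere cavities without
    deleting tesserae, so the energy stays a continuous function of the
    geometry.  Regular tesserae are far enough apart that the cap is
    inactive for them.
    """
    pos = cavity.positions
    n = len(pos)
    if n == 0:
        raise CpcmError("cavity has no tesserae")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    off = dist[np.triu_indices(n, 1)]
    if off.size and off.min() < 1e-8:
        raise CpcmError("degenerate cavity: coincident tesserae")
    with np.errstate(divide="ignore"):
        d = 1.0 / dist
    diag = diagonal_constant * np.sqrt(4.0 * math.pi / cavity.areas)
    cap = OFFDIAGONAL_SATURATION * np.sqrt(np.outer(diag, diag))
    np.minimum(d, cap, out=d)
    d[np.arange(n), np.arange(n)] = diag
    return d


def nuclear_potential(mol: Molecule, cavity: Cavity, params: ParameterSet) -> np.ndarray:
    """V_i^nuc = sum_A Z_A / |s_i - R_A| (au), Z_A the valence core charge."""
    z = np.array([params[s].zval for s in mol.symbols], dtype=float)
    diff = cavity.positions[:, None, :] - mol.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if dist.min() < 0.1:
        logger.warning(
            "tessera within 0.1 bohr of a nucleus (min distance %.3g)", dist.min()
        )
    return (z[None, :] / dist).sum(axis=1)


def _multipole_scalars(par, r):
    """The four unique local-frame potentials (au) at distances r (array),
    with Klopman-Ohno terms set to zero and near-field clamping."""
    clamp = NEAR_FIELD_CLAMP

    def inv(x):
        return 1.0 / np.maximum(x, clamp)

    v_ss = inv(r)
    if par.n_orbitals == 1:
        return v_ss, None, None, None
    d1, d2 = par.d1, par.d2
    v_sp = 0.5 * (inv(r - d1) - inv(r + d1))
    v_sig = 0.5 * inv(r) + 0.25 * (inv(r - 2 * d2) + inv(r + 2 * d2))
    v_pi = 0.5 * inv(r) + 0.5 / np.sqrt(np.maximum(r * r + 4 * d2 * d2, clamp**2))
    return v_ss, v_sp, v_sig, v_pi


def tessera_integral_block(par, rvec) -> np.ndarray:
    """<mu nu>_i block (au) for one atom against a unit charge at offset
    rvec = s_i - R_A (bohr)."""
    r = float(np.linalg.norm(rvec))
    if r <= 0.0:
        raise CpcmError("tessera coincides with a nucleus")
    blocks = tessera_integral_blocks(par, np.asarray(rvec, float)[None, :])
    return blocks[0]


def tessera_integral_blocks(par, rvecs: np.ndarray) -> np.ndarray:
    """Vectorized <mu nu> blocks (n_tess, n_orb, n_orb) in au.

    rvecs[i] points from the atom to tessera i; the local z-axis of the
    multipole frame lies along it, and the rotation onto the molecular frame
    uses the direction cosines e = rvec/|rvec|.
    """
    r = np.linalg.norm(rvecs, axis=1)
    e = rvecs / r[:, None]
    n = par.n_orbitals
    out = np.zeros((len(r), n, n))
    v_ss, v_sp, v_sig, v_pi = _multipole_scalars(par, r)
    out[:, 0, 0] = v_ss
    if n == 1:
        return out
    out[:, 0, 1:] = e * v_sp[:, None]
    out[:, 1:, 0] = out[:, 0, 1:]
    ee = np.einsum("ti,tj->tij", e, e)
    eye = np.eye(3)[None, :, :]
    out[:, 1:, 1:] = ee * (v_sig - v_pi)[:, None, None] + eye * v_pi[:, None, None]
    return out


def solute_integral_blocks(mol: Molecule, params: ParameterSet, positions: np.ndarray) -> np.ndarray:
    """Full (n_points, n_basis, n_basis) interaction-integral array (au)."""
    basis = Basis(mol, params)
    nb = basis.n_orbitals
    out = np.zeros((len(positions), nb, nb))
    for a in range(mol.natoms):
        sl = basis.atom_slice(a)
        out[:, sl, sl] = tessera_integral_blocks(
            basis.atom_params[a], positions - mol.coords[a][None, :]
        )
    return out


def electronic_potential(density: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """V_i^el = -sum_mu,nu P_mu,nu <mu nu>_i (au)."""
    if blocks.shape[1:] != density.shape:
        raise CpcmError("density / integral-block dimension mismatch")
    return -np.einsum("tij,ij->t", blocks, density)


def solve_asc(
    d_matrix,
    potential: np.ndarray,
    f: float,
    mode: str = "direct",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Solve D q = -f V for the apparent surface charges.

    ``d_matrix`` may be a dense array or a prefactored Cholesky pair.
    Iterative mode uses Jacobi-preconditioned conjugate gradients with an
    absolute residual-norm tolerance.
    """
    rhs = -f * potential
    if mode == "direct":
        if isinstance(d_matrix, tuple):
            return cho_solve(d_matrix, rhs)
        return cho_solve(cho_factor(d_matrix), rhs)
    if mode != "iterative":
        raise ValueError(f"unknown ASC solver mode {mode!r}")
    d = d_matrix
    diag = np.diag(d)
    m = LinearOperator(d.shape, matvec=lambda x: x / diag)
    q, info = cg(d, rhs, rtol=0.0, atol=tol, maxiter=max_iter, M=m)
    if info != 0:
        res = float(np.linalg.norm(d @ q - rhs))
        raise CpcmError(f"iterative ASC solve did not converge (residual {res:.3e})")
    return q


def pcm_fock_contribution(q: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    """F^PCM_mu,nu = -sum_i q_i <mu nu>_i (au)."""
    return -np.einsum("t,tij->ij", q, blocks)


def electrostatic_free_energy(q: np.ndarray, potential: np.ndarray) -> float:
    """Solute-solvent electrostatic interaction free energy (kcal/mol)."""
    return 0.5 * float(q @ potential) * EV * EVKCAL


@dataclass
class CpcmAttachment:
    """Per-SCF-iteration C-PCM quantities retained on the SCF state."""

    cavity: Cavity
    solvent: SolventModel
    f: float
    potential: np.ndarray  # au, total V at tesserae
    nuclear_potential: np.ndarray
    charges: np.ndarray  # au
    dg_el_kcal: float  # 0.5 q.V

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def to_csv(self, path) -> None:
        """Per-tessera dump: position, area, V_nuc, V_el, q."""
        cav = self.cavity
        with open(path, "w") as fh:
            fh.write("index,x,y,z,area,v_nuc,v_el,q\n")
            for i in range(cav.n_tesserae):
                x, y, z = cav.positions[i]
                vn = self.nuclear_potential[i]
                fh.write(
                    f"{i},{x:.8f},{y:.8f},{z:.8f},{cav.areas[i]:.8f},"
                    f"{vn:.10f},{self.potential[i] - vn:.10f},{self.charges[i]:.10f}\n"
                )


# switch to iterative ASC solves above this tessera count (dense
# factorization becomes the bottleneck, CG with Jacobi preconditioning
# converges fast)
_DIRECT_SOLVER_LIMIT = 2500

# Floor on the eigenvalues of D in the direct solver (au).  Interlocked
# GEPOL spheres occasionally produce a near-null surface-charge mode
# (clusters of seam tesserae closer than their size warrants); inverting
# through such a mode overscreens catastrophically and acts as a spurious
# energy sink during geometry optimization.  Healthy cavities have minimum
# eigenvalues well above this floor, so it is inactive for them.
EIGENVALUE_FLOOR = 0.25


def floored_solve(eigendecomposition, rhs: np.ndarray) -> np.ndarray:
    w, u = eigendecomposition
    return u @ ((u.T @ rhs) / w)


def floored_eigendecomposition(d: np.ndarray, floor: float = EIGENVALUE_FLOOR):
    """Eigendecomposition of D with a smooth lower bound on the spectrum.

    w' = floor + [(w - floor) + sqrt((w - floor)^2 + floor^2)]/2 tends to w
    for w >> floor and saturates smoothly at the floor from above, so the
    regularized energy stays a smooth function of the geometry (a hard
    max(w, floor) puts kinks on the surface exactly where optimizers land).
    """
    w, u = np.linalg.eigh(d)
    shifted = w - floor
    wreg = floor + 0.5 * (shifted + np.sqrt(shifted * shifted + floor * floor))
    return wreg, u


class CpcmSystem:
    """Geometry-bound C-PCM engine providing the SCF hook.

    Precomputes the D matrix (factored), the nuclear potential and the
    basis-tessera integral blocks once per geometry; per SCF iteration only
    the electronic potential, the ASC solve and the Fock contraction run.
    """

    def __init__(
        self,
        mol: Molecule,
        params: ParameterSet,
        cavity: Cavity,
        solvent: SolventModel = WATER,
        diagonal_constant: float = DIAGONAL_CONSTANT,
        solver_mode: str | None = None,
    ):
        self.mol = mol
        self.params = params
        self.cavity = cavity
        self.solvent = solvent
        self.f = dielectric_scale(solvent)
        self.d_matrix = build_cpcm_matrix(cavity, diagonal_constant)
        n = cavity.n_tesserae
        if solver_mode is None:
            solver_mode = "direct" if n <= _DIRECT_SOLVER_LIMIT else "iterative"
        self.solver_mode = solver_mode
        self._eig = (
            floored_eigendecomposition(self.d_matrix) if solver_mode == "direct" else None
        )
        self._last_q = None
        self.v_nuc = nuclear_potential(mol, cavity, params)
        self.blocks = solute_integral_blocks(mol, params, cavity.positions)

    def potential(self, density: np.ndarray) -> np.ndarray:
        return self.v_nuc + electronic_potential(density, self.blocks)

    def charges(self, potential: np.ndarray) -> np.ndarray:
        if self.solver_mode == "direct":
            return floored_solve(self._eig, -self.f * potential)
        # iterative, warm-started across SCF iterations
        d = self.d_matrix
        diag = np.diag(d)
        m = LinearOperator(d.shape, matvec=lambda x: x / diag)
        q, info = cg(
            d, -self.f * potential, x0=self._last_q, rtol=0.0, atol=1e-8, maxiter=2000, M=m
        )
        if info != 0:
            res = float(np.linalg.norm(d @ q + self.f * potential))
            raise CpcmError(f"iterative ASC solve did not converge (residual {res:.3e})")
        self._last_q = q
        return q

    def hook(self, density: np.ndarray):
        """SCF callback: (F_pcm in eV, interaction energy in eV, attachment)."""
        v = self.potential(density)
        q = self.charges(v)
        e_pcm_ev = 0.5 * float(q @ v) * EV
        f_pcm_ev = EV * pcm_fock_contribution(q, self.blocks)
        att = CpcmAttachment(
            cavity=self.cavity,
            solvent=self.solvent,
            f=self.f,
            potential=v,
            nuclear_potential=self.v_nuc,
            charges=q,
            dg_el_kcal=e_pcm_ev * EVKCAL,
        )
        return f_pcm_ev, e_pcm_ev, att


def solvated_scf(
    mol: Molecule,
    params: ParameterSet,
    solvent: SolventModel = WATER,
    n_per_sphere: int = 60,
    radii_table: dict | None = None,
    radii_scale: float = 1.2,
    frame: np.ndarray | None = None,
    cavity: Cavity | None = None,
    options=None,
    p0=None,
):
    """Converge the SCF in the C-PCM reaction field.

    Returns the SCF state; state.pcm carries the cavity, charges and the
    interaction free energy, and state.total_energy includes 0.5 q.V.
    """
    from .cavity import build_cavity
    from .nddo import scf

    if cavity is None:
        cavity = build_cavity(mol, n_per_sphere, radii_table, radii_scale, frame)
    system = CpcmSystem(mol, params, cavity, solvent)
    return scf(mol, params, options, pcm_hook=system.hook, p0=p0)
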