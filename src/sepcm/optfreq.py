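"""Geometry optimization (Cartesian BFGS), double-difference Hessians,
harmonic frequencies and the solvated-vs-gas frequency deviation statistic.

Energies are in hartree and gradients in hartree/bohr throughout this
module; convergence follows the maximum absolute gradient component
(threshold 5e-4 au by default).  Optimizations that repeatedly fail to find
a descent step are reported as stalled — a legitimate outcome on noisy
regions of the PCM surface — with the best geometry retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .molecule import Molecule
from .units import EV, FREQ_AU_TO_CM1

logger = logging.getLogger(__name__)

OPT_THRESHOLD = 5e-4  # au/bohr, maximum gradient component


@dataclass
class OptimizationResult:
    molecule: Molecule  # final geometry
    energy: float  # hartree
    steps: int
    converged: bool
    stalled: bool
    max_gradient: float
    trajectory: list = field(default_factory=list)  # (coords, energy, gmax)
    hessian_approx: np.ndarray | None = None  # final BFGS curvature model


def optimize(
    mol: Molecule,
    energy_gradient_fn,
    threshold: float = OPT_THRESHOLD,
    max_steps: int = 100,
    max_step_size: float = 0.3,  # bohr, per-component trust cap
    hessian_update: bool = True,
    initial_hessian: np.ndarray | None = None,
) -> OptimizationResult:
    """Quasi-Newton minimization on Cartesian coordinates.

    ``energy_gradient_fn(mol) -> (energy_hartree, gradient)`` where
    ``gradient`` is either the (natoms, 3) array in au/bohr or a callable
    returning it — the lazy form lets expensive gradients be skipped at
    rejected line-search points.  BFGS with a unit initial Hessian (or a
    supplied curvature model, e.g. from a preceding gas-phase run);
    ``hessian_update=False`` freezes it, mirroring the skip-update
    workaround for stalling small-molecule PCM optimizations.
    """
    n = mol.natoms * 3
    x = mol.coords.ravel().copy()
    b = np.eye(n) if initial_hessian is None else initial_hessian.copy()

    def evaluate(m):
        e, g = energy_gradient_fn(m)
        if callable(g):
            g = g()
        return e, np.asarray(g, float).ravel()

    e, g = evaluate(mol)
    trajectory = [(x.copy().reshape(-1, 3), e, float(np.abs(g).max()))]
    stalls = 0
    converged = False
    stalled = False
    steps = 0
    for steps in range(1, max_steps + 1):
        gmax = float(np.abs(g).max())
        if gmax < threshold:
            converged = True
            steps -= 1
            break
        p = np.linalg.solve(b, -g)
        pmax = float(np.abs(p).max())
        if pmax > max_step_size:
            p *= max_step_size / pmax
        # backtracking acceptance on the energy alone
        accepted = False
        scale = 1.0
        for _ in range(6):
            x_new = x + scale * p
            try:
                e_new, g_lazy = energy_gradient_fn(mol.with_coords(x_new.reshape(-1, 3)))
            except Exception:
                scale *= 0.25
                continue
            if e_new <= e + 1e-12:
                accepted = True
                break
            scale *= 0.25
        if not accepted:
            stalls += 1
            logger.info("optimizer found no descent step (stall %d)", stalls)
            if stalls >= 2:
                stalled = True
                break
            continue
        stalls = 0
        s = scale * p
        g_new = np.asarray(g_lazy() if callable(g_lazy) else g_lazy, float).ravel()
        y = g_new - g
        if hessian_update:
            sy = float(s @ y)
            if sy > 1e-10:
                bs = b @ s
                b = b + np.outer(y, y) / sy - np.outer(bs, bs) / float(s @ bs)
        x = x_new
        e, g = e_new, g_new
        trajectory.append((x.copy().reshape(-1, 3), e, float(np.abs(g).max())))
    final = mol.with_coords(x.reshape(-1, 3))
    return OptimizationResult(
        molecule=final,
        energy=e,
        steps=steps,
        converged=converged,
        stalled=stalled,
        max_gradient=float(np.abs(g).max()),
        trajectory=trajectory,
        hessian_approx=b,
    )


def hessian_double_difference(mol: Molecule, gradient_fn, step: float = 0.01):
    """Symmetrized central-difference Hessian (au/bohr^2) from gradients.

    Returns (hessian, asymmetry) where asymmetry is the max |H - H^T|
    element before symmetrization — a consistency diagnostic.
    """
    n = mol.natoms * 3
    h = np.zeros((n, n))
    x0 = mol.coords.ravel()
    for i in range(n):
        cols = []
        for sgn in (1.0, -1.0):
            x = x0.copy()
            x[i] += sgn * step
            cols.append(gradient_fn(mol.with_coords(x.reshape(-1, 3))).ravel())
        h[:, i] = (cols[0] - cols[1]) / (2.0 * step)
    asym = float(np.abs(h - h.T).max())
    return 0.5 * (h + h.T), asym


@dataclass
class FrequencySet:
    frequencies: np.ndarray  # cm^-1 sorted ascending; negatives = imaginary
    n_imaginary: int
    modes: np.ndarray  # mass-weighted normal modes, columns
    rigid_frequencies: np.ndarray  # |freq| of the projected-out modes

    @property
    def vibrational(self) -> np.ndarray:
        return self.frequencies


def _rigid_body_space(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (columns)."""
    n = len(coords)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    rel = coords - com
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = sqm
        vecs.append(t.ravel())
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        r = np.cross(rel, axis) * sqm[:, None]
        vecs.append(r.ravel())
    v = np.array(vecs).T  # (3n, 6)
    # orthonormalize, dropping null rotations (linear molecules, atoms)
    qmat, rmat = np.linalg.qr(v)
    keep = np.abs(np.diag(rmat)) > 1e-8
    return qmat[:, keep]


def frequencies(hessian: np.ndarray, masses: np.ndarray, coords: np.ndarray) -> FrequencySet:
    """Harmonic frequencies (cm^-1) from a Cartesian Hessian (au/bohr^2).

    Mass-weights, projects out rigid translations/rotations, diagonalizes;
    imaginary modes are returned as negative wavenumbers.
    """
    sqm = np.sqrt(np.repeat(masses, 3))
    h_mw = hessian / np.outer(sqm, sqm)
    rigid = _rigid_body_space(coords, masses)
    proj = np.eye(len(sqm)) - rigid @ rigid.T
    h_proj = proj @ h_mw @ proj
    lam, vec = np.linalg.eigh(h_proj)

    def to_cm(l):
        return float(np.sign(l) * FREQ_AU_TO_CM1 * np.sqrt(abs(l) * EV))

    nrigid = rigid.shape[1]
    order = np.argsort(np.abs(lam))
    rigid_idx = order[:nrigid]
    vib_idx = np.sort(order[nrigid:])
    freqs = np.array([to_cm(lam[i]) for i in vib_idx])
    srt = np.argsort(freqs)
    return FrequencySet(
        frequencies=freqs[srt],
        n_imaginary=int((freqs < 0.0).sum()),
        modes=vec[:, vib_idx][:, srt],
        rigid_frequencies=np.array([abs(to_cm(lam[i])) for i in rigid_idx]),
    )


def mad_frequencies(solvated: FrequencySet, gas: FrequencySet, include_imaginary: bool = False) -> float:
    """Mean absolute deviation (cm^-1) between index-paired sorted spectra.

    Imaginary modes are excluded by default (their counts are available on
    the inputs); a count mismatch after filtering must be resolved by the
    caller and raises.
    """
    a = np.sort(solvated.frequencies)
    b = np.sort(gas.frequencies)
    if not include_imaginary:
        a = a[a > 0.0]
        b = b[b > 0.0]
    if len(a) != len(b):
        raise ValueError(
            f"vibrational counts differ ({len(a)} vs {len(b)}); "
            "resolve imaginary-mode handling before pairing"
        )
    if len(a) == 0:
        return 0.0
    return float(np.mean(np.abs(a - b)))
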