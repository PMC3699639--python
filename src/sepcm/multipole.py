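"""NDDO two-center two-electron integrals by the point-multipole method.

Each one-center charge distribution chi_mu * chi_nu is represented by point
multipoles in a frame whose z-axis joins the two interaction centers:

* (s,s)            -> monopole, charge +1 at the nucleus
* (s,p_a)          -> dipole, charges +-1/2 at +-D1 along axis a
* (p_a,p_a)        -> monopole +1, plus linear quadrupole
                      {+1/4 at +-2*D2 along a, -1/2 at the nucleus}
* (p_a,p_b), a!=b  -> square quadrupole, charges +-1/4 at the corners
                      (+-D2 a_hat +- D2 b_hat)

Two configurations interact through the Klopman-Ohno damped Coulomb kernel
1/sqrt(r^2 + (rho_l(A) + rho_l'(B))^2), which interpolates between 1/r at
long range and the correct one-center integral at r = 0.  The local-frame
10x10 block is rotated to the molecular frame by transforming the p
orbitals as vectors.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .units import EV

# symmetric pair index for a 4-orbital (s, px, py, pz) atom: 10 pairs
PAIR_INDEX = [(i, j) for i in range(4) for j in range(i, 4)]


def _charge_config(par):
    """Point-charge pieces for every orbital pair of one atom (local frame).

    Returns {(mu, nu): [(l, [(q, xyz), ...]), ...]} with xyz in bohr.
    """
    if par.n_orbitals == 1:
        return {(0, 0): [(0, [(1.0, np.zeros(3))])]}
    d1, d2 = par.d1, par.d2
    axes = np.eye(3)
    cfg = {(0, 0): [(0, [(1.0, np.zeros(3))])]}
    for a in range(3):
        ea = axes[a]
        cfg[(0, a + 1)] = [(1, [(0.5, d1 * ea), (-0.5, -d1 * ea)])]
        cfg[(a + 1, a + 1)] = [
            (0, [(1.0, np.zeros(3))]),
            (2, [(0.25, 2 * d2 * ea), (0.25, -2 * d2 * ea), (-0.5, np.zeros(3))]),
        ]
        for b in range(a + 1, 3):
            eb = axes[b]
            cfg[(a + 1, b + 1)] = [
                (2, [
                    (0.25, d2 * (ea + eb)),
                    (0.25, -d2 * (ea + eb)),
                    (-0.25, d2 * (ea - eb)),
                    (-0.25, -d2 * (ea - eb)),
                ])
            ]
    return cfg


@lru_cache(maxsize=64)
def _pair_tables(par_a, par_b):
    """Flattened interaction tables for one ordered element pair.

    Precomputes, over all charge pairs of all distribution pairs, the
    charge products, local-frame offsets, squared damping radii and the
    scatter index into the (npair_a, npair_b) local integral block.
    """
    cfg_a = _charge_config(par_a)
    cfg_b = _charge_config(par_b)
    rho_a = (par_a.rho0, par_a.rho1, par_a.rho2)
    rho_b = (par_b.rho0, par_b.rho1, par_b.rho2)
    pairs_a = sorted(cfg_a)
    pairs_b = sorted(cfg_b)
    qprod, off_a, off_b, rho2, idx = [], [], [], [], []
    for ia, ka in enumerate(pairs_a):
        for ib, kb in enumerate(pairs_b):
            for la, charges_a in cfg_a[ka]:
                for lb, charges_b in cfg_b[kb]:
                    rr = (rho_a[la] + rho_b[lb]) ** 2
                    for qa, xa in charges_a:
                        for qb, xb in charges_b:
                            qprod.append(qa * qb)
                            off_a.append(xa)
                            off_b.append(xb)
                            rho2.append(rr)
                            idx.append(ia * len(pairs_b) + ib)
    return (
        np.array(qprod),
        np.array(off_a),
        np.array(off_b),
        np.array(rho2),
        np.array(idx),
        pairs_a,
        pairs_b,
    )


def local_repulsion_block(par_a, par_b, r: float) -> np.ndarray:
    """(mu nu | la si) local-frame block in eV; B sits at (0, 0, r) bohr.

    The in-plane quadrupole integral (p_x p_y | p_x p_y) is replaced by the
    cylinder identity (pp'|pp') = [(pp|pp) - (pp|p'p')]/2, which the finite
    square-quadrupole point-charge realization satisfies only approximately;
    with the identity enforced the rotated two-center tensor is exactly
    invariant under rotations of the molecule (and under the arbitrary x/y
    completion of the local frame).
    """
    qprod, off_a, off_b, rho2, idx, pairs_a, pairs_b = _pair_tables(par_a, par_b)
    delta = off_b + np.array([0.0, 0.0, r]) - off_a
    vals = qprod / np.sqrt(np.einsum("ij,ij->i", delta, delta) + rho2)
    flat = np.zeros(len(pairs_a) * len(pairs_b))
    np.add.at(flat, idx, vals)
    block = EV * flat.reshape(len(pairs_a), len(pairs_b))
    if len(pairs_a) == 10 and len(pairs_b) == 10:
        # pair indices: 4 = (px,px), 5 = (px,py), 7 = (py,py)
        block[5, 5] = 0.5 * (block[4, 4] - block[4, 7])
    return block


def _expand_block(block, pairs_a, pairs_b, na, nb):
    """Symmetric-pair block -> full (na, na, nb, nb) tensor."""
    g = np.zeros((na, na, nb, nb))
    for ia, (i, j) in enumerate(pairs_a):
        for ib, (k, l) in enumerate(pairs_b):
            v = block[ia, ib]
            g[i, j, k, l] = g[j, i, k, l] = g[i, j, l, k] = g[j, i, l, k] = v
    return g


def rotation_matrix(rvec: np.ndarray, n_orb: int) -> np.ndarray:
    """Orbital rotation O with O[i, a] = mol_axis_i . local_axis_a.

    Local z lies along rvec; x and y are a deterministic orthonormal
    completion (the final rotated integrals do not depend on the choice).
    """
    if n_orb == 1:
        return np.ones((1, 1))
    ez = np.asarray(rvec, float) / np.linalg.norm(rvec)
    ref = np.zeros(3)
    ref[np.argmin(np.abs(ez))] = 1.0
    ex = np.cross(ref, ez)
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    o = np.eye(n_orb)
    o[1:, 1:] = np.column_stack([ex, ey, ez])  # columns are local axes
    return o


def two_center_repulsion(par_a, par_b, rvec) -> np.ndarray:
    """Molecular-frame two-electron tensor (na, na, nb, nb) in eV.

    rvec points from atom A to atom B (bohr); orbital order s[, px, py, pz].
    """
    r = float(np.linalg.norm(rvec))
    if r < 1e-3:
        raise ValueError("overlapping nuclei in two-electron integral evaluation")
    qprod, off_a, off_b, rho2, idx, pairs_a, pairs_b = _pair_tables(par_a, par_b)
    block = local_repulsion_block(par_a, par_b, r)
    na, nb = par_a.n_orbitals, par_b.n_orbitals
    g_loc = _expand_block(block, pairs_a, pairs_b, na, nb)
    oa = rotation_matrix(rvec, na)
    ob = rotation_matrix(rvec, nb)
    ka = np.kron(oa, oa)
    kb = np.kron(ob, ob)
    g = ka @ g_loc.reshape(na * na, nb * nb) @ kb.T
    return g.reshape(na, na, nb, nb)


def one_center_repulsion(par) -> np.ndarray:
    """One-center two-electron tensor (n, n, n, n) in eV from g/h parameters."""
    n = par.n_orbitals
    g = np.zeros((n, n, n, n))
    g[0, 0, 0, 0] = par.gss
    if n == 1:
        return g
    hpp = 0.5 * (par.gpp - par.gp2)
    for p in range(1, 4):
        g[0, 0, p, p] = g[p, p, 0, 0] = par.gsp
        g[p, p, p, p] = par.gpp
        g[0, p, 0, p] = g[p, 0, 0, p] = g[0, p, p, 0] = g[p, 0, p, 0] = par.hsp
        for q in range(1, 4):
            if p != q:
                g[p, p, q, q] = par.gp2
                g[p, q, p, q] = g[p, q, q, p] = hpp
    return g
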