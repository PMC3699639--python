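"""Analytic overlap integrals between Slater-type orbitals (1s, 2s, 2p).

Overlaps are evaluated exactly in prolate-spheroidal coordinates
(mu = (r_a + r_b)/R, nu = (r_a - r_b)/R): the product of two STOs reduces to
a bivariate polynomial in (mu, nu) times exp(-p mu - q nu), and the integral
separates into the classical auxiliary functions

    A_j(p) = int_1^inf  mu^j exp(-p mu) d mu
    B_k(q) = int_-1^1   nu^k exp(-q nu) d nu

The polynomial is assembled numerically (no hand-expanded special cases),
which keeps the code generic over the seven (n l m) combinations needed for
an s,p valence basis.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

_SQ3 = math.sqrt(3.0)


def aux_a(jmax: int, p: float) -> np.ndarray:
    """A_j(p) for j = 0..jmax (p > 0)."""
    out = np.empty(jmax + 1)
    ep = math.exp(-p)
    out[0] = ep / p
    for j in range(1, jmax + 1):
        out[j] = ep / p + j * out[j - 1] / p
    return out


def aux_b(kmax: int, q: float) -> np.ndarray:
    """B_k(q) for k = 0..kmax, stable for all q via a power series."""
    out = np.empty(kmax + 1)
    if abs(q) < 18.0:
        # B_k = sum_m (-q)^m/m! * (1 + (-1)^(k+m)) / (k+m+1)
        for k in range(kmax + 1):
            term = 1.0
            s = 0.0
            m = 0
            while True:
                if (k + m) % 2 == 0:
                    s += term * 2.0 / (k + m + 1)
                m += 1
                term *= -q / m
                if m > 12 and abs(term) < 1e-17 * (abs(s) + 1e-300):
                    break
                if m > 200:  # pragma: no cover
                    break
            out[k] = s
    else:
        eq, emq = math.exp(q), math.exp(-q)
        out[0] = (eq - emq) / q
        for k in range(1, kmax + 1):
            out[k] = ((-1) ** k * eq - emq) / q + k * out[k - 1] / q
    return out


# --- tiny dense bivariate polynomial helpers: c[j, k] <-> mu^j nu^k ---

def _pmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.zeros((a.shape[0] + b.shape[0] - 1, a.shape[1] + b.shape[1] - 1))
    for j in range(a.shape[0]):
        for k in range(a.shape[1]):
            if a[j, k] != 0.0:
                out[j : j + b.shape[0], k : k + b.shape[1]] += a[j, k] * b
    return out


def _pdiv_linear(c: np.ndarray, sign: float) -> np.ndarray:
    """Exact division of c by (mu + sign*nu)."""
    nj, nk = c.shape
    q = np.zeros((nj - 1, nk))
    rem = c.copy()
    for j in range(nj - 1, 0, -1):
        row = rem[j].copy()
        q[j - 1] += row
        rem[j] -= row
        rem[j - 1, 1:] -= sign * row[:-1]
    if not np.allclose(rem, 0.0, atol=1e-10):  # pragma: no cover
        raise ValueError("polynomial not divisible; unsupported (n,l,m) combination")
    return q


_ONE = np.array([[1.0]])
_MU_PLUS_NU = np.array([[0.0, 1.0], [1.0, 0.0]])  # nu + mu
_MU_MINUS_NU = np.array([[0.0, -1.0], [1.0, 0.0]])
_ONE_PLUS_MUNU = np.array([[1.0, 0.0], [0.0, 1.0]])  # 1 + mu*nu
_MUNU_MINUS_ONE = np.array([[-1.0, 0.0], [0.0, 1.0]])
# (mu^2 - 1)(1 - nu^2)
_SIN_FACTOR = _pmul(
    np.array([[-1.0], [0.0], [1.0]]), np.array([[1.0, 0.0, -1.0]])
)


def _radial_norm(n: int, zeta: float) -> float:
    return (2.0 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


@lru_cache(maxsize=4096)
def _local_overlap_poly(na, la, ma, nb, lb, mb):
    """Polynomial coefficients and angular prefactor for a local-frame pair."""
    if ma != mb:
        return None  # sigma-pi overlaps vanish by symmetry
    poly = _ONE
    for _ in range(na - 1):
        poly = _pmul(poly, _MU_PLUS_NU)
    for _ in range(nb - 1):
        poly = _pmul(poly, _MU_MINUS_NU)
    ndiv_plus = ndiv_minus = 0
    ang = 1.0 / (4.0 * math.pi)  # product of the two S_lm normalizations
    if la == 1:
        ang *= _SQ3
    if lb == 1:
        ang *= _SQ3
    if abs(ma) == 1:  # pi-pi
        poly = _pmul(poly, _SIN_FACTOR)
        ndiv_plus += 1
        ndiv_minus += 1
        phi = math.pi
    else:
        if la == 1:
            poly = _pmul(poly, _ONE_PLUS_MUNU)
            ndiv_plus += 1
        if lb == 1:
            poly = _pmul(poly, _MUNU_MINUS_ONE)
            ndiv_minus += 1
        phi = 2.0 * math.pi
    # volume element (mu^2 - nu^2) = (mu+nu)(mu-nu)
    poly = _pmul(poly, _pmul(_MU_PLUS_NU, _MU_MINUS_NU))
    for _ in range(ndiv_plus):
        poly = _pdiv_linear(poly, 1.0)
    for _ in range(ndiv_minus):
        poly = _pdiv_linear(poly, -1.0)
    return poly, ang * phi


def sto_overlap_local(na, la, ma, zeta_a, nb, lb, mb, zeta_b, r):
    """<a|b> with atom a at the origin, b at (0, 0, r) bohr, both orbital
    axes along +z (m is the common |m| with matching real component)."""
    got = _local_overlap_poly(na, la, ma, nb, lb, mb)
    if got is None:
        return 0.0
    poly, pref = got
    p = 0.5 * r * (zeta_a + zeta_b)
    q = 0.5 * r * (zeta_a - zeta_b)
    aj = aux_a(poly.shape[0] - 1, p)
    bk = aux_b(poly.shape[1] - 1, q)
    val = float(aj @ poly @ bk)
    norm = _radial_norm(na, zeta_a) * _radial_norm(nb, zeta_b)
    return norm * pref * (0.5 * r) ** (na + nb + 1) * val


def diatomic_overlap(par_a, par_b, rvec) -> np.ndarray:
    """Overlap block between the valence orbitals of two atoms.

    Parameters
    ----------
    par_a, par_b : ElementParameters
    rvec : 3-vector from atom a to atom b (bohr)

    Returns an (n_a, n_b) array in the molecular frame with orbital order
    (s[, px, py, pz]).
    """
    r = float(np.linalg.norm(rvec))
    e = np.asarray(rvec, dtype=float) / r
    na_orb, nb_orb = par_a.n_orbitals, par_b.n_orbitals
    out = np.zeros((na_orb, nb_orb))
    s_ss = sto_overlap_local(par_a.nq, 0, 0, par_a.zeta_s, par_b.nq, 0, 0, par_b.zeta_s, r)
    out[0, 0] = s_ss
    if nb_orb > 1:
        s_spz = sto_overlap_local(par_a.nq, 0, 0, par_a.zeta_s, par_b.nq, 1, 0, par_b.zeta_p, r)
        out[0, 1:] = s_spz * e
    if na_orb > 1:
        s_pzs = sto_overlap_local(par_a.nq, 1, 0, par_a.zeta_p, par_b.nq, 0, 0, par_b.zeta_s, r)
        out[1:, 0] = s_pzs * e
    if na_orb > 1 and nb_orb > 1:
        s_sig = sto_overlap_local(par_a.nq, 1, 0, par_a.zeta_p, par_b.nq, 1, 0, par_b.zeta_p, r)
        s_pi = sto_overlap_local(par_a.nq, 1, 1, par_a.zeta_p, par_b.nq, 1, 1, par_b.zeta_p, r)
        ee = np.outer(e, e)
        out[1:, 1:] = ee * s_sig + (np.eye(3) - ee) * s_pi
    return out
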