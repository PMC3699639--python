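"""NDDO parameter sets (MNDO, AM1, PM3) for H, C, N, O.

Published element constants are stored in JSON data files; the quantities
derived from them — the multipole charge separations D1/D2 and the
Klopman–Ohno additive radii rho0/rho1/rho2 — are recomputed here from the
Slater exponents and one-center integrals by the standard NDDO recipes:

* D1 = <2s| z |2pz> for Slater orbitals, the dipole length of the sp
  charge distribution,
* D2 = sqrt((2n+1)(2n+2)/20) / zeta_p, half the charge separation of the
  pp quadrupole,
* rho0 from [q,q](0) = g_ss, rho1 from [mu,mu](0) = h_sp, rho2 from the
  square-quadrupole self-interaction [Q,Q](0) = (g_pp - g_p2)/2,

so the parameter files carry only the primary published numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from scipy.optimize import brentq

from .units import EV

SUPPORTED_METHODS = ("MNDO", "AM1", "PM3")
SUPPORTED_ELEMENTS = ("H", "C", "N", "O")


class UnsupportedParameterError(KeyError):
    """Requested method or element has no embedded parameter set."""


@dataclass(frozen=True)
class ElementParameters:
    """Complete per-element NDDO parameter record.

    Energies in eV, Slater exponents in bohr^-1, alpha in angstrom^-1,
    multipole separations and rho terms in bohr, heats in kcal/mol.
    """

    symbol: str
    atomic_number: int
    zval: int  # valence core charge Z_A
    nq: int  # principal quantum number of the valence shell
    uss: float
    upp: float
    zeta_s: float
    zeta_p: float
    beta_s: float
    beta_p: float
    alpha: float
    gss: float
    gsp: float
    gpp: float
    gp2: float
    hsp: float
    gaussian_terms: tuple  # ((K, L, M), ...) core-repulsion corrections
    eisol: float  # atomic ground-state electronic energy (eV)
    eheat: float  # experimental atomic heat of formation (kcal/mol)
    # derived
    d1: float = 0.0
    d2: float = 0.0
    rho0: float = 0.0
    rho1: float = 0.0
    rho2: float = 0.0

    @property
    def n_orbitals(self) -> int:
        return 1 if self.symbol == "H" else 4

    @property
    def valence_occupations(self) -> tuple:
        """Formal atomic orbital occupations (s, px, py, pz) of the neutral atom."""
        if self.symbol == "H":
            return (1.0,)
        p = (self.zval - 2) / 3.0
        return (2.0, p, p, p)


def _d1(zs: float, zp: float, n: int) -> float:
    """Dipole length <ns| z |np> of two Slater orbitals with the same n."""
    return (
        (2 * n + 1)
        * (4.0 * zs * zp) ** (n + 0.5)
        / (math.sqrt(3.0) * (zs + zp) ** (2 * n + 2))
    )


def _d2(zp: float, n: int) -> float:
    """Half separation of the pp quadrupole point charges."""
    return math.sqrt((2 * n + 1) * (2 * n + 2) / 20.0) / zp


def _solve_rho1(d1: float, hsp_au: float) -> float:
    """rho1 from the coaxial dipole-dipole one-center limit.

    Two +-1/2 point-charge dipoles of length 2*D1 on the same center,
    Klopman-Ohno damped by 2*rho1, must interact with energy h_sp.
    """

    def f(r):
        return 0.25 * (1.0 / r - 1.0 / math.sqrt(d1 * d1 + r * r)) - hsp_au

    return brentq(f, 1e-4, 50.0, xtol=1e-12)


def _solve_rho2(d2: float, hpp_au: float) -> float:
    """rho2 from the square-quadrupole one-center limit [Qxz,Qxz](0) = hpp."""

    def f(r):
        return (
            1.0 / (8.0 * r)
            - 1.0 / (4.0 * math.sqrt(d2 * d2 + r * r))
            + 1.0 / (8.0 * math.sqrt(2.0 * d2 * d2 + r * r))
            - hpp_au
        )

    return brentq(f, 1e-4, 50.0, xtol=1e-12)


def _finalize(symbol: str, rec: dict) -> ElementParameters:
    zs, zp, n = rec["zs"], rec["zp"], rec["nq"]
    if symbol == "H":
        d1 = d2 = 0.0
        rho1 = rho2 = 0.0
    else:
        d1 = _d1(zs, zp, n)
        d2 = _d2(zp, n)
        rho1 = _solve_rho1(d1, rec["hsp"] / EV)
        rho2 = _solve_rho2(d2, 0.5 * (rec["gpp"] - rec["gp2"]) / EV)
    rho0 = 0.5 * EV / rec["gss"]
    return ElementParameters(
        symbol=symbol,
        atomic_number=rec["z"],
        zval=rec["zval"],
        nq=n,
        uss=rec["uss"],
        upp=rec["upp"],
        zeta_s=zs,
        zeta_p=zp,
        beta_s=rec["betas"],
        beta_p=rec["betap"],
        alpha=rec["alpha"],
        gss=rec["gss"],
        gsp=rec["gsp"],
        gpp=rec["gpp"],
        gp2=rec["gp2"],
        hsp=rec["hsp"],
        gaussian_terms=tuple(tuple(g) for g in rec["gaussians"]),
        eisol=rec["eisol"],
        eheat=rec["eheat"],
        d1=d1,
        d2=d2,
        rho0=rho0,
        rho1=rho1,
        rho2=rho2,
    )


@dataclass(frozen=True)
class ParameterSet:
    method: str
    elements: dict = field(default_factory=dict)  # symbol -> ElementParameters

    def __getitem__(self, symbol: str) -> ElementParameters:
        try:
            return self.elements[symbol]
        except KeyError:
            raise UnsupportedParameterError(
                f"no {self.method} parameters loaded for element {symbol!r}"
            ) from None


def load_parameters(method: str, elements=SUPPORTED_ELEMENTS) -> ParameterSet:
    """Load a complete NDDO parameter set for the requested elements.

    Parameters
    ----------
    method : {"MNDO", "AM1", "PM3"}
    elements : iterable of element symbols, subset of {H, C, N, O}
    """
    method = method.upper()
    if method not in SUPPORTED_METHODS:
        raise UnsupportedParameterError(
            f"unsupported method {method!r}; choose from {SUPPORTED_METHODS}"
        )
    with resources.files("sepcm.data.params").joinpath(f"{method.lower()}.json").open() as fh:
        table = json.load(fh)
    out = {}
    for sym in elements:
        if sym not in table["elements"]:
            raise UnsupportedParameterError(
                f"element {sym!r} has no published {method} parameters in this package"
            )
        out[sym] = _finalize(sym, table["elements"][sym])
    return ParameterSet(method=method, elements=out)
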