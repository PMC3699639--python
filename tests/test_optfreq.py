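import math

import numpy as np
import pytest

from sepcm import Molecule, load_parameters, scf
from sepcm.nddo import SCFError
from sepcm.optfreq import (
    FrequencySet,
    frequencies,
    hessian_double_difference,
    mad_frequencies,
    optimize,
)
from sepcm.solvation_gradient import gas_gradient
from sepcm.units import BOHR_TO_ANGSTROM, EV, FREQ_AU_TO_CM1, MASSES
from tests.conftest import molecule


def _gas_eg(params):
    def eg(m):
        state = scf(m, params)
        if not state.converged:
            raise SCFError("unconverged")
        return state.total_energy / EV, gas_gradient(m, params, state)

    return eg


def _gas_grad(params):
    def g(m):
        return gas_gradient(m, params, scf(m, params))

    return g


def test_optimize_quadratic_bowl_converges_fast():
    center = np.array([[0.3, -0.2, 0.1]])

    def eg(m):
        d = m.coords - center
        return float(np.sum(d * d)), 2.0 * d

    res = optimize(Molecule(("H",), np.zeros((1, 3)), charge=-1), eg, max_steps=50)
    assert res.converged
    assert np.allclose(res.molecule.coords, center, atol=1e-3)


def test_optimize_from_minimum_terminates_immediately(h2, pm3):
    eg = _gas_eg(pm3)
    first = optimize(h2, eg, max_steps=60)
    assert first.converged
    again = optimize(first.molecule, eg, max_steps=5)
    assert again.converged and again.steps <= 1


def test_h2_pm3_equilibrium_bond_length(h2, pm3):
    res = optimize(h2, _gas_eg(pm3), max_steps=60)
    assert res.converged
    r = np.linalg.norm(res.molecule.coords[1] - res.molecule.coords[0]) * BOHR_TO_ANGSTROM
    # PM3 H2: published bond length 0.699 angstrom
    assert r == pytest.approx(0.699, abs=0.002)


def test_frozen_hessian_option_still_descends(h2, pm3):
    res = optimize(h2, _gas_eg(pm3), max_steps=80, hessian_update=False)
    assert res.converged


def test_hessian_exact_on_quadratic():
    k = np.diag([1.0, 2.0, 3.0])

    def grad(m):
        return (m.coords.ravel() * np.diag(k)).reshape(1, 3)

    mol = Molecule(("H",), np.array([[0.1, 0.2, 0.3]]), charge=-1)
    h, asym = hessian_double_difference(mol, grad, step=0.02)
    assert np.allclose(h, k, atol=1e-10)
    assert asym < 1e-12


def test_water_has_three_real_modes_and_clean_projection(h2o, pm3):
    res = optimize(h2o, _gas_eg(pm3), threshold=1e-4, max_steps=80)
    assert res.converged
    mol = res.molecule
    hess, asym = hessian_double_difference(mol, _gas_grad(pm3))
    # the gradient itself is a central difference (step 1e-3 bohr), so the
    # double-difference asymmetry carries that noise floor
    assert asym < 1e-4
    fs = frequencies(hess, mol.masses, mol.coords)
    assert len(fs.frequencies) == 3
    assert fs.n_imaginary == 0
    assert (fs.rigid_frequencies < 5.0).all()
    # water: two stretches near 3900 and a bend near 1700 (PM3 scale)
    assert fs.frequencies[0] < 2500 < fs.frequencies[1]


def test_h2_frequency_against_1d_oracle(h2, pm3):
    """Independent oracle: second derivative of E(R) on a 1D grid plus the
    diatomic reduced-mass formula."""
    res = optimize(h2, _gas_eg(pm3), threshold=1e-5, max_steps=60)
    mol = res.molecule
    hess, _ = hessian_double_difference(mol, _gas_grad(pm3))
    fs = frequencies(hess, mol.masses, mol.coords)
    assert len(fs.frequencies) == 1  # linear molecule: 3N - 5

    r0 = np.linalg.norm(mol.coords[1] - mol.coords[0])
    h = 0.01

    def e_of_r(r):
        m = mol.with_coords(np.array([[0, 0, 0], [0, 0, r]]))
        return scf(m, pm3).total_energy / EV

    k = (e_of_r(r0 + h) - 2 * e_of_r(r0) + e_of_r(r0 - h)) / h**2  # hartree/bohr^2
    mu = MASSES["H"] / 2.0
    nu = FREQ_AU_TO_CM1 * math.sqrt(k * EV / mu)
    assert fs.frequencies[0] == pytest.approx(nu, abs=5.0)


def test_single_atom_has_no_vibrations():
    fs = frequencies(np.zeros((3, 3)), np.array([12.011]), np.zeros((1, 3)))
    assert len(fs.frequencies) == 0


def test_saddle_point_reports_imaginary_mode():
    # hand-built Hessian with one negative eigenvalue on a fake diatomic
    coords = np.array([[0, 0, 0], [0, 0, 1.4]])
    masses = np.array([1.008, 1.008])
    h = np.zeros((6, 6))
    # stretch coordinate along z with negative curvature
    for i, j, v in [(2, 2, -0.3), (5, 5, -0.3), (2, 5, 0.3), (5, 2, 0.3)]:
        h[i, j] = v
    fs = frequencies(h, masses, coords)
    assert fs.n_imaginary >= 1
    assert fs.frequencies[0] < 0


def test_mad_arithmetic_and_permutation_safety():
    a = FrequencySet(np.array([100.0, 200.0]), 0, np.empty(0), np.empty(0))
    b = FrequencySet(np.array([190.0, 110.0]), 0, np.empty(0), np.empty(0))
    assert mad_frequencies(a, a) == 0.0
    assert mad_frequencies(a, b) == pytest.approx(10.0)


def test_mad_count_mismatch_raises():
    a = FrequencySet(np.array([100.0, 200.0]), 0, np.empty(0), np.empty(0))
    c = FrequencySet(np.array([-50.0, 120.0, 210.0]), 1, np.empty(0), np.empty(0))
    # after dropping the imaginary mode the counts match
    assert mad_frequencies(a, c) == pytest.approx(15.0)
    d = FrequencySet(np.array([120.0, 210.0, 300.0]), 0, np.empty(0), np.empty(0))
    with pytest.raises(ValueError):
        mad_frequencies(a, d)


def test_unconverged_optimization_reports_not_raises(h2, pm3):
    res = optimize(h2.with_coords(h2.coords * 1.8), _gas_eg(pm3), max_steps=1)
    assert not res.converged
    assert res.steps <= 1
    assert res.trajectory
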