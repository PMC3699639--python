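import numpy as np
import pytest

from sepcm import (
    ElectronicStructure,
    GeometryError,
    Molecule,
    SCFError,
    SCFOptions,
    build_core_hamiltonian,
    core_core_repulsion,
    heat_of_formation,
    load_parameters,
    numerical_gradient,
    scf,
)
from sepcm.nddo import core_gradient_pairwise
from sepcm.optfreq import optimize
from sepcm.solvation_gradient import gas_gradient
from sepcm.units import ANGSTROM_TO_BOHR, EV
from tests.conftest import molecule, random_rotation

# Heats of formation reported by the original MNDO/AM1/PM3 parameterization
# papers for molecules at their optimized geometries (kcal/mol).  These are
# method-defining outputs: reproducing them validates the entire integral,
# SCF and core-repulsion stack.
PUBLISHED_HOF = {
    ("PM3", "CH4"): -13.0,
    ("PM3", "H2O"): -53.4,
    ("PM3", "NH3"): -3.1,
    ("AM1", "CH4"): -8.8,
    ("AM1", "H2O"): -59.2,
    ("MNDO", "CH4"): -11.9,
    ("MNDO", "H2O"): -60.9,
}


def _optimized_hof(mol, method):
    params = load_parameters(method)

    def eg(m):
        state = scf(m, params)
        assert state.converged
        return state.total_energy / EV, gas_gradient(m, params, state)

    res = optimize(mol, eg, threshold=2e-4, max_steps=80)
    assert res.converged
    return scf(res.molecule, params).heat_of_formation


@pytest.mark.parametrize("method,name", sorted(PUBLISHED_HOF))
def test_optimized_heats_of_formation_match_published_values(
    method, name, ch4, h2o, nh3
):
    mol = {"CH4": ch4, "H2O": h2o, "NH3": nh3}[name]
    hof = _optimized_hof(mol, method)
    assert hof == pytest.approx(PUBLISHED_HOF[(method, name)], abs=0.1)


def test_single_hydrogen_core_matrix(pm3):
    # hydride keeps the electron count even for the closed-shell machinery
    h = build_core_hamiltonian(Molecule(("H",), np.zeros((1, 3)), charge=-1), pm3)
    assert h.shape == (1, 1)
    assert h[0, 0] == pytest.approx(pm3["H"].uss)


def test_distant_h2_limits(pm3):
    far = molecule(["H", "H"], [[0, 0, 0], [0, 0, 50.0]])
    h = build_core_hamiltonian(far, pm3)
    assert abs(h[0, 1]) < 1e-12  # resonance decays with overlap
    r_bohr = 50.0 * ANGSTROM_TO_BOHR
    e_core = core_core_repulsion(far, pm3)
    assert e_core / EV == pytest.approx(1.0 / r_bohr, rel=1e-3)


def test_overlapping_nuclei_rejected(pm3):
    with pytest.raises(GeometryError):
        ElectronicStructure(molecule(["H", "H"], [[0, 0, 0], [0, 0, 1e-5]]), pm3)


def test_odd_electron_count_rejected(pm3):
    with pytest.raises(GeometryError):
        ElectronicStructure(molecule(["H", "H", "H"], [[0, 0, 0], [0, 0, 1], [0, 1, 0]]), pm3)


def test_electron_count_conserved(nh4_cation, pm3):
    state = scf(nh4_cation, pm3)
    assert state.converged
    assert np.trace(state.density) == pytest.approx(8.0, abs=1e-10)


def test_diis_and_plain_scf_agree(h2o, pm3):
    """The accelerator changes the SCF path, not its fixed point."""
    from sepcm.pipeline import load_fixture

    for mol in (h2o, load_fixture("A1"), load_fixture("O8")):
        e1 = scf(mol, pm3, SCFOptions(diis=True)).total_energy
        e2 = scf(mol, pm3, SCFOptions(diis=False)).total_energy
        assert e1 == pytest.approx(e2, abs=1e-6)


def test_energy_invariant_under_rigid_motion(h2o, pm3):
    rng = np.random.default_rng(11)
    e0 = scf(h2o, pm3).total_energy
    q = random_rotation(rng)
    moved = h2o.with_coords(h2o.coords @ q.T + np.array([5.0, 5.0, 5.0]) * ANGSTROM_TO_BOHR)
    e1 = scf(moved, pm3).total_energy
    assert e1 == pytest.approx(e0, abs=1e-7)


def test_hof_translation_invariance(ch4, pm3):
    s0 = scf(ch4, pm3)
    s1 = scf(ch4.with_coords(ch4.coords + 5.0 * ANGSTROM_TO_BOHR), pm3)
    assert s1.heat_of_formation == pytest.approx(s0.heat_of_formation, abs=1e-8)


def test_hof_refuses_unconverged(h2o, pm3):
    state = scf(h2o, pm3, SCFOptions(max_iter=1))
    assert not state.converged
    with pytest.raises(SCFError):
        heat_of_formation(state, h2o, pm3)


def test_single_carbon_hof_is_atomic_reference(pm3):
    # a single C atom (4 valence electrons, closed-shell treatment of the
    # fractional-occupation reference) reproduces EISOL by construction
    mol = Molecule(("C",), np.zeros((1, 3)), charge=0)
    es = ElectronicStructure(mol, pm3)
    # no pairs: total energy is the one-center energy of the reference density
    assert es.core_repulsion == 0.0


def test_numerical_gradient_richardson_consistency(h2o, pm3):
    def efn(m):
        state = scf(m, pm3)
        if not state.converged:
            raise SCFError("unconverged")
        return state.total_energy

    g3 = numerical_gradient(efn, h2o, step=1e-3) / EV
    g4 = numerical_gradient(efn, h2o, step=1e-4) / EV
    assert np.abs(g3 - g4).max() < 1e-5


def test_pairwise_core_gradient_matches_full_rebuild(h2o, pm3):
    state = scf(h2o, pm3)
    gp = core_gradient_pairwise(h2o, pm3, state.density)
    # oracle: central differences of the full fixed-density energy
    step = 1e-3
    gf = np.zeros_like(gp)
    for a in range(h2o.natoms):
        for k in range(3):
            vals = []
            for sgn in (1.0, -1.0):
                x = h2o.coords.copy()
                x[a, k] += sgn * step
                es = ElectronicStructure(h2o.with_coords(x), pm3)
                vals.append(es.energy(state.density))
            gf[a, k] = (vals[0] - vals[1]) / (2 * step)
    assert np.abs(gp - gf).max() < 1e-9


def test_gradient_positive_for_stretched_h2(pm3):
    stretched = molecule(["H", "H"], [[0, 0, 0], [0, 0, 0.9]])
    state = scf(stretched, pm3)
    g = gas_gradient(stretched, pm3, state)
    # dE/dR > 0 past the minimum: force on atom 2 points along +z
    assert g[1, 2] > 0
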