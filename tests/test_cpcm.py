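import math

import numpy as np
import pytest

from sepcm import Molecule, load_parameters, scf
from sepcm.cavity import Sphere, build_cavity, tessellate_gepol
from sepcm.cpcm import (
    CpcmError,
    CpcmSystem,
    SolventModel,
    WATER,
    build_cpcm_matrix,
    dielectric_scale,
    electronic_potential,
    electrostatic_free_energy,
    nuclear_potential,
    pcm_fock_contribution,
    solvated_scf,
    solve_asc,
    solute_integral_blocks,
    tessera_integral_block,
)
from sepcm.units import ANGSTROM_TO_BOHR, EVKCAL, EV, HARTREE_KCAL
from tests.conftest import molecule, random_rotation


# --- dielectric scaling ----------------------------------------------------

def test_dielectric_scale_limits():
    assert dielectric_scale(SolventModel(1.0)) == 0.0
    assert dielectric_scale(SolventModel(1e9)) == pytest.approx(1.0, abs=1e-8)
    assert dielectric_scale(WATER) == pytest.approx(0.98724, abs=1e-5)
    alt = SolventModel(78.39, "eps+0.5")
    assert dielectric_scale(alt) == pytest.approx(77.39 / 78.89, rel=1e-12)


def test_dielectric_scale_domain():
    with pytest.raises(ValueError):
        SolventModel(0.5)


# --- the C-PCM matrix ------------------------------------------------------

def test_matrix_off_diagonal_is_inverse_distance():
    d_ang = 2.0
    cav = _toy_cavity([[0, 0, 0], [0, 0, d_ang * ANGSTROM_TO_BOHR]])
    d = build_cpcm_matrix(cav)
    assert d[0, 1] == pytest.approx(1.0 / (d_ang * ANGSTROM_TO_BOHR), rel=1e-12)
    assert d[0, 1] == pytest.approx(0.26459, abs=1e-4)


def test_matrix_diagonal_formula():
    cav = _toy_cavity([[0, 0, 0]], areas=[4 * math.pi])
    d = build_cpcm_matrix(cav, diagonal_constant=1.0694)
    assert d[0, 0] == pytest.approx(1.0694, rel=1e-12)


def test_matrix_positive_definite_for_dense_sphere():
    cav = tessellate_gepol([Sphere(0, np.zeros(3), 3.0)], 960, frame=np.eye(3))
    d = build_cpcm_matrix(cav)
    np.linalg.cholesky(d)  # raises if not positive definite


def test_coincident_tesserae_rejected():
    cav = _toy_cavity([[0, 0, 0], [0, 0, 1e-10]])
    with pytest.raises(CpcmError):
        build_cpcm_matrix(cav)


def _toy_cavity(positions, areas=None):
    positions = np.asarray(positions, float)
    n = len(positions)
    areas = np.ones(n) if areas is None else np.asarray(areas, float)
    return type(
        "ToyCavity",
        (),
        {
            "positions": positions,
            "areas": areas,
            "n_tesserae": n,
            "sphere_index": np.zeros(n, dtype=int),
            "spheres": [Sphere(0, np.zeros(3), 1.0)],
        },
    )()


# --- potentials and integrals ---------------------------------------------

def test_nuclear_potential_point_charge(pm3):
    mol = Molecule(("H",), np.zeros((1, 3)), charge=-1)
    cav = _toy_cavity([[0, 0, 1.0]])
    v = nuclear_potential(mol, cav, pm3)
    assert v[0] == pytest.approx(1.0)


def test_nuclear_potential_positive_for_cation(nh4_cation, pm3):
    cav = build_cavity(nh4_cation, 60)
    v = nuclear_potential(nh4_cation, cav, pm3)
    assert (v > 0).all()


def test_tessera_block_hydrogen_is_bare_monopole(pm3):
    r = 3.7
    block = tessera_integral_block(pm3["H"], np.array([0.0, 0.0, r]))
    assert block.shape == (1, 1)
    assert block[0, 0] == pytest.approx(1.0 / r, rel=1e-12)


def test_tessera_block_local_frame_zero_pattern(pm3):
    block = tessera_integral_block(pm3["C"], np.array([0.0, 0.0, 4.0]))
    assert block[0, 1] == 0.0 and block[0, 2] == 0.0  # s-px, s-py vanish on the z-axis
    assert block[0, 3] != 0.0
    assert np.allclose(block, block.T)


def _point_charge_oracle(par, r):
    """Explicit point-charge configurations for the four unique integrals."""
    d1, d2 = par.d1, par.d2
    v_ss = 1.0 / r
    v_spz = 0.5 / (r - d1) - 0.5 / (r + d1)
    v_pzpz = 0.5 / r + 0.25 / (r - 2 * d2) + 0.25 / (r + 2 * d2)
    v_pipi = 0.5 / r + 0.5 / math.sqrt(r * r + 4 * d2 * d2)
    return v_ss, v_spz, v_pzpz, v_pipi


def test_multipole_limits_at_long_range(pm3):
    """R*V_ss -> 1; R^2*V_spz -> D1 (the finite +-D1 charge pair deviates
    from the ideal dipole by D1^3/R^2, so the bare-limit check sits at
    R = 100 bohr while the R = 20 values match the explicit point-charge
    configurations exactly)."""
    c = pm3["C"]
    r = 20.0
    block = tessera_integral_block(c, np.array([0.0, 0.0, r]))
    assert abs(r * block[0, 0] - 1.0) < 1e-6
    far = tessera_integral_block(c, np.array([0.0, 0.0, 100.0]))
    assert abs(100.0**2 * far[0, 3] - c.d1) < 1e-4
    v_ss, v_spz, v_pzpz, v_pipi = _point_charge_oracle(c, r)
    assert block[0, 0] == pytest.approx(v_ss, rel=1e-12)
    assert block[0, 3] == pytest.approx(v_spz, rel=1e-12)
    assert block[3, 3] == pytest.approx(v_pzpz, rel=1e-12)
    assert block[1, 1] == pytest.approx(v_pipi, rel=1e-12)


def test_electronic_potential_zero_density(pm3, h2o):
    cav = build_cavity(h2o, 60)
    blocks = solute_integral_blocks(h2o, pm3, cav.positions)
    v = electronic_potential(np.zeros(blocks.shape[1:]), blocks)
    assert np.allclose(v, 0.0)


def test_electronic_potential_dimension_mismatch(pm3, h2o):
    cav = build_cavity(h2o, 60)
    blocks = solute_integral_blocks(h2o, pm3, cav.positions)
    with pytest.raises(CpcmError):
        electronic_potential(np.zeros((2, 2)), blocks)


def test_neutral_molecule_far_field_screened(pm3, h2o):
    state = scf(h2o, pm3)
    point = np.array([[100.0 * ANGSTROM_TO_BOHR, 0.0, 0.0]])
    blocks = solute_integral_blocks(h2o, pm3, point)
    cav = _toy_cavity(point)
    v = nuclear_potential(h2o, cav, pm3) + electronic_potential(state.density, blocks)
    assert abs(v[0]) < 1e-4


# --- ASC solution and energies ---------------------------------------------

def born_setup(n=960, r_ang=2.0):
    r = r_ang * ANGSTROM_TO_BOHR
    cav = tessellate_gepol([Sphere(0, np.zeros(3), r)], n, frame=np.eye(3))
    d = build_cpcm_matrix(cav)
    v = 1.0 / np.linalg.norm(cav.positions, axis=1)
    return cav, d, v, r


def test_asc_zero_potential_gives_zero_charges():
    cav, d, v, _ = born_setup(60)
    q = solve_asc(d, np.zeros_like(v), dielectric_scale(WATER))
    assert np.allclose(q, 0.0)


def test_gauss_law_for_born_sphere():
    f = dielectric_scale(WATER)
    cav, d, v, _ = born_setup()
    q = solve_asc(d, v, f)
    assert q.sum() == pytest.approx(-f, rel=0.015)


def test_born_free_energy_within_two_percent():
    f = dielectric_scale(WATER)
    cav, d, v, r = born_setup()
    q = solve_asc(d, v, f)
    dg = electrostatic_free_energy(q, v)
    born = -0.5 * f / r * HARTREE_KCAL
    assert dg == pytest.approx(born, rel=0.02)
    assert dg == pytest.approx(-81.9, abs=2.0)


def test_born_convergence_with_tessera_density():
    f = dielectric_scale(WATER)
    errs = []
    for n in (60, 240, 960):
        cav, d, v, r = born_setup(n)
        q = solve_asc(d, v, f)
        born = -0.5 * f / r * HARTREE_KCAL
        errs.append(abs(electrostatic_free_energy(q, v) - born))
    assert errs[2] <= errs[0]
    assert errs[2] / abs(-0.5 * f / (2.0 * ANGSTROM_TO_BOHR) * HARTREE_KCAL) < 0.02


def test_iterative_solver_matches_direct():
    f = dielectric_scale(WATER)
    cav, d, v, _ = born_setup()
    q1 = solve_asc(d, v, f, "direct")
    q2 = solve_asc(d, v, f, "iterative")
    assert np.abs(q1 - q2).max() < 1e-6


def test_unknown_solver_mode():
    cav, d, v, _ = born_setup(60)
    with pytest.raises(ValueError):
        solve_asc(d, v, 0.9, "magic")


def test_fock_contribution_zero_charges(pm3, h2o):
    cav = build_cavity(h2o, 60)
    blocks = solute_integral_blocks(h2o, pm3, cav.positions)
    assert np.allclose(pcm_fock_contribution(np.zeros(cav.n_tesserae), blocks), 0.0)


def test_fock_contribution_single_tessera_sign(pm3):
    blocks = tessera_integral_block(pm3["H"], np.array([0.0, 0.0, 1.0]))[None]
    f = pcm_fock_contribution(np.array([-1.0]), blocks)
    assert f[0, 0] == pytest.approx(1.0)  # -q * <ss> = +1 au


def test_free_energy_zero_for_vacuum(nh4_cation, pm3):
    state = solvated_scf(nh4_cation, pm3, SolventModel(1.0), n_per_sphere=60)
    assert state.converged
    assert state.pcm.dg_el_kcal == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(state.pcm.charges, 0.0)


def test_cation_stabilized_in_water(nh4_cation, pm3):
    gas = scf(nh4_cation, pm3)
    sol = solvated_scf(nh4_cation, pm3, n_per_sphere=60)
    assert sol.converged
    assert sol.total_energy < gas.total_energy
    assert sol.pcm.dg_el_kcal < -60.0


def test_self_consistency_of_final_charges(nh4_cation, pm3):
    sol = solvated_scf(nh4_cation, pm3, n_per_sphere=60)
    system = CpcmSystem(nh4_cation, pm3, sol.pcm.cavity)
    v = system.potential(sol.density)
    q = system.charges(v)
    dg = 0.5 * float(q @ v) * EV * EVKCAL
    assert dg == pytest.approx(sol.pcm.dg_el_kcal, abs=1e-6)


def test_frame_invariance_of_interaction_energy(nh4_cation, pm3):
    rng = np.random.default_rng(17)
    sol0 = solvated_scf(nh4_cation, pm3, n_per_sphere=60)
    qrot = random_rotation(rng)
    moved = nh4_cation.with_coords(nh4_cation.coords @ qrot.T + 3.0)
    sol1 = solvated_scf(moved, pm3, n_per_sphere=60)
    assert sol1.pcm.dg_el_kcal == pytest.approx(sol0.pcm.dg_el_kcal, abs=0.01)


def test_gauss_law_for_solvated_cation(nh4_cation, pm3):
    sol = solvated_scf(nh4_cation, pm3, n_per_sphere=960)
    f = sol.pcm.f
    assert sol.pcm.total_charge == pytest.approx(-f, abs=0.02 * f)


def test_tessera_csv_dump(tmp_path, nh4_cation, pm3):
    sol = solvated_scf(nh4_cation, pm3, n_per_sphere=60)
    path = tmp_path / "tess.csv"
    sol.pcm.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == sol.pcm.cavity.n_tesserae + 1
    assert lines[0].startswith("index,")
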