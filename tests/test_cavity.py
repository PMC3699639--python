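import math

import numpy as np
import pytest

from sepcm import Molecule
from sepcm.cavity import (
    CavityError,
    Sphere,
    assign_radii,
    build_cavity,
    cavity_displacement_rebuild,
    molecular_frame,
    tessellate_gepol,
)
from sepcm.units import ANGSTROM_TO_BOHR
from tests.conftest import molecule, random_rotation


def two_sphere_union_area(r1, r2, d):
    c1 = (d * d + r1 * r1 - r2 * r2) / (2 * d * r1)
    c2 = (d * d + r2 * r2 - r1 * r1) / (2 * d * r2)
    return 2 * math.pi * r1 * r1 * (1 + c1) + 2 * math.pi * r2 * r2 * (1 + c2)


def test_assign_radii_scaling(pm3):
    mol = Molecule(("C",), np.zeros((1, 3)))
    spheres = assign_radii(mol, scale=1.2)
    assert spheres[0].radius == pytest.approx(1.70 * 1.2 * ANGSTROM_TO_BOHR)


def test_assign_radii_errors():
    mol = Molecule(("C",), np.zeros((1, 3)))
    with pytest.raises(CavityError):
        assign_radii(mol, scale=0.0)
    with pytest.raises(CavityError):
        assign_radii(mol, radii_table={"H": 1.2})


def test_nh4_has_five_spheres_nitrogen_largest(nh4_cation):
    spheres = assign_radii(nh4_cation)
    assert len(spheres) == 5
    assert spheres[0].radius == max(s.radius for s in spheres)


@pytest.mark.parametrize("n", [60, 240, 960])
def test_isolated_sphere_area_closure(n):
    r = 2.5
    cav = tessellate_gepol([Sphere(0, np.zeros(3), r)], n, frame=np.eye(3))
    exact = 4 * math.pi * r * r
    assert cav.n_tesserae == n
    assert abs(cav.total_area - exact) / exact < 5e-3


def test_refinement_does_not_worsen_closure():
    r = 2.0
    errs = []
    for n in (60, 960):
        cav = tessellate_gepol([Sphere(0, np.zeros(3), r)], n, frame=np.eye(3))
        errs.append(abs(cav.total_area - 4 * math.pi * r * r))
    assert errs[1] <= errs[0] + 1e-9


@pytest.mark.parametrize("d", [0.8, 1.5, 2.2, 2.9, 3.4])
def test_two_sphere_union_matches_analytic(d):
    r1, r2 = 2.0, 1.5
    spheres = [Sphere(0, np.zeros(3), r1), Sphere(1, np.array([0.0, 0.0, d]), r2)]
    cav = tessellate_gepol(spheres, 240, frame=np.eye(3))
    exact = two_sphere_union_area(r1, r2, d)
    assert cav.total_area == pytest.approx(exact, rel=1e-6)


def test_coincident_identical_spheres_collapse_to_one():
    spheres = [Sphere(0, np.zeros(3), 2.0), Sphere(1, np.zeros(3), 2.0)]
    cav = tessellate_gepol(spheres, 240, frame=np.eye(3))
    assert cav.total_area == pytest.approx(16 * math.pi, rel=1e-10)


def test_buried_sphere_contributes_nothing():
    spheres = [Sphere(0, np.zeros(3), 3.0), Sphere(1, np.array([0.2, 0, 0]), 0.5)]
    cav = tessellate_gepol(spheres, 60, frame=np.eye(3))
    assert set(cav.sphere_index.tolist()) == {0}


def test_rotation_invariance_of_total_area(nh4_cation):
    rng = np.random.default_rng(5)
    cav0 = build_cavity(nh4_cation, 60)
    q = random_rotation(rng)
    rot = nh4_cation.with_coords(nh4_cation.coords @ q.T)
    cav1 = build_cavity(rot, 60)
    assert cav1.total_area == pytest.approx(cav0.total_area, rel=1e-9)
    assert cav1.n_tesserae == cav0.n_tesserae


def test_no_representative_point_strictly_inside_other_sphere(h2o):
    cav = build_cavity(molecule(["O", "H", "H"], [[0, 0, 0.06], [0, 0.76, -0.47], [0, -0.76, -0.47]]), 240)
    for i in range(cav.n_tesserae):
        p = cav.positions[i]
        for j, s in enumerate(cav.spheres):
            if j == cav.sphere_index[i]:
                continue
            assert np.linalg.norm(p - s.center) >= s.radius - 1e-7


def test_tessera_points_lie_on_parent_spheres(nh4_cation):
    cav = build_cavity(nh4_cation, 60)
    for i in range(cav.n_tesserae):
        s = cav.spheres[cav.sphere_index[i]]
        assert np.linalg.norm(cav.positions[i] - s.center) == pytest.approx(s.radius, abs=1e-8)
    normals = cav.normals
    assert np.allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-10)


def test_displacement_rebuild_identity_and_translation(nh4_cation):
    cav = build_cavity(nh4_cation, 60)
    same = cavity_displacement_rebuild(cav, nh4_cation)
    assert np.array_equal(same.positions, cav.positions)
    assert np.array_equal(same.areas, cav.areas)
    shift = np.array([1.0, -2.0, 0.5])
    moved = cavity_displacement_rebuild(cav, nh4_cation.with_coords(nh4_cation.coords + shift))
    assert np.allclose(moved.positions, cav.positions + shift, atol=1e-10)
    assert np.allclose(moved.areas, cav.areas, atol=1e-10)


def test_rebuild_area_changes_continuously():
    """Two-sphere oracle: the tessellated area change under a small
    displacement tracks the analytic derivative of the union area."""
    r1, r2, d = 2.0, 1.5, 2.4
    spheres = [Sphere(0, np.zeros(3), r1), Sphere(1, np.array([0.0, 0.0, d]), r2)]
    cav = tessellate_gepol(spheres, 240, frame=np.eye(3))
    h = 1e-4
    mol = Molecule(("C", "C"), np.array([[0, 0, 0], [0, 0, d]]))
    up = cavity_displacement_rebuild(cav, mol.with_coords(np.array([[0, 0, 0], [0, 0, d + h]])))
    dn = cavity_displacement_rebuild(cav, mol.with_coords(np.array([[0, 0, 0], [0, 0, d - h]])))
    fd = (up.total_area - dn.total_area) / (2 * h)
    analytic = (
        two_sphere_union_area(r1, r2, d + h) - two_sphere_union_area(r1, r2, d - h)
    ) / (2 * h)
    assert fd == pytest.approx(analytic, rel=1e-4, abs=1e-6)


def test_molecular_frame_is_rotation_equivariant(nh4_cation):
    rng = np.random.default_rng(9)
    q = random_rotation(rng)
    f0 = molecular_frame(nh4_cation.coords)
    f1 = molecular_frame(nh4_cation.coords @ q.T)
    # frame axes must co-rotate: f1 = f0 @ q.T
    assert np.allclose(f1, f0 @ q.T, atol=1e-10)


def test_invalid_tessera_count_rejected():
    with pytest.raises(CavityError):
        tessellate_gepol([Sphere(0, np.zeros(3), 1.0)], 100)


def test_cavity_csv_dump(tmp_path, nh4_cation):
    cav = build_cavity(nh4_cation, 60)
    path = tmp_path / "cavity.csv"
    cav.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "index,sphere,x,y,z,area"
    assert len(lines) == cav.n_tesserae + 1
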