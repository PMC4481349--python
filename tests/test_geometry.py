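import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_

from lipidgate.geometry import (
    AtomRecord,
    AtomSelection,
    FrameCoordinates,
    center_of_mass,
    contour_length,
    dihedral_angle,
    dihedral_angles,
    end_to_end_distance,
    group_min_distance,
    mass_for_element,
    select,
)

from conftest import make_atoms, random_rigid_transform


def frame(positions, time=0.0):
    return FrameCoordinates(time, np.asarray(positions, dtype=float))


def selection(indices, masses):
    return AtomSelection(np.asarray(indices), np.asarray(masses))


# --- center of mass -----------------------------------------------------

@pytest.mark.parametrize(
    "masses, positions, expected",
    [
        ([5.0], [(1, 2, 3)], (1, 2, 3)),
        ([2.0, 2.0], [(0, 0, 0), (2, 0, 0)], (1, 0, 0)),
        ([1.0, 3.0], [(0, 0, 0), (4, 0, 0)], (3, 0, 0)),
    ],
)
def test_center_of_mass_weighted_mean(masses, positions, expected):
    sel = selection(range(len(masses)), masses)
    com = center_of_mass(sel, frame(positions))
    assert np.allclose(com, expected)


def test_center_of_mass_empty_selection_errors():
    with pytest.raises(ValueError, match="empty selection"):
        center_of_mass(selection([], []), frame(np.zeros((1, 3))))


def test_center_of_mass_rigid_motion_equivariant():
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(6, 3))
    masses = rng.uniform(1, 20, size=6)
    sel = selection(range(6), masses)
    com = center_of_mass(sel, frame(pos))
    for _ in range(5):
        R, t = random_rigid_transform(rng)
        com2 = center_of_mass(sel, frame(pos @ R.T + t))
        assert np.allclose(com2, R @ com + t, atol=1e-9)


def test_center_of_mass_invariant_under_atom_reordering():
    rng = np.random.default_rng(1)
    pos = rng.normal(size=(5, 3))
    masses = rng.uniform(1, 16, size=5)
    com = center_of_mass(selection(range(5), masses), frame(pos))
    perm = rng.permutation(5)
    com_p = center_of_mass(selection(perm, masses[perm]), frame(pos))
    assert np.allclose(com, com_p)


# --- group minimum distance ---------------------------------------------

@pytest.mark.parametrize("mode", ["com_per_residue", "atom_pair"])
def test_group_min_distance_singleton_residues(mode):
    pos = [(0, 0, 0), (5, 0, 0), (0, 7, 0), (0, 0, 9)]
    probe = selection([0], [12.0])
    residues = [selection([i], [12.0]) for i in (1, 2, 3)]
    d = group_min_distance(probe, residues, frame(pos), mode=mode)
    assert d == pytest.approx(5.0)


def test_group_min_distance_modes_differ_on_extended_residue():
    pos = [(0, 0, 0), (3, 0, 0), (5, 0, 0)]
    probe = selection([0], [12.0])
    residues = [selection([1, 2], [12.0, 12.0])]
    f = frame(pos)
    assert group_min_distance(probe, residues, f, "com_per_residue") == pytest.approx(4.0)
    assert group_min_distance(probe, residues, f, "atom_pair") == pytest.approx(3.0)


def test_group_min_distance_atom_pair_equals_exhaustive_minimum():
    rng = np.random.default_rng(2)
    pos = rng.normal(scale=8.0, size=(30, 3))
    f = frame(pos)
    probe = selection(range(10), np.ones(10))
    residues = [selection(range(10, 20), np.ones(10)),
                selection(range(20, 30), np.ones(10))]
    got = group_min_distance(probe, residues, f, "atom_pair")
    brute = min(
        np.linalg.norm(pos[i] - pos[j])
        for i in range(10)
        for j in range(10, 30)
    )
    assert got == pytest.approx(brute, abs=1e-12)


def test_group_min_distance_permutation_invariant_and_nonnegative():
    rng = np.random.default_rng(3)
    pos = rng.normal(scale=5.0, size=(12, 3))
    f = frame(pos)
    probe = selection([0, 1], np.ones(2))
    residues = [selection([i, i + 1], np.ones(2)) for i in (2, 4, 6, 8)]
    for mode in ("com_per_residue", "atom_pair"):
        d1 = group_min_distance(probe, residues, f, mode)
        d2 = group_min_distance(probe, residues[::-1], f, mode)
        assert d1 == d2 >= 0


def test_group_min_distance_empty_residue_list_errors():
    with pytest.raises(ValueError):
        group_min_distance(selection([0], [1.0]), [], frame(np.zeros((1, 3))))


# --- dihedral angle -----------------------------------------------------

def _dihedral_rotation_oracle(p1, p2, p3, p4):
    """Independent torsion computation: rotate the central bond onto +z,
    then take the signed planar angle between the projected outer bonds."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    b2 = b2 / np.linalg.norm(b2)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(b2, z)
    s = np.linalg.norm(v)
    c = np.dot(b2, z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    u = (R @ (p1 - p2))[:2]
    w = (R @ (p4 - p3))[:2]
    ang = np.degrees(np.arctan2(u[0] * w[1] - u[1] * w[0], u @ w))
    return ang if ang > -180.0 else 180.0


@pytest.mark.parametrize(
    "pts, expected",
    [
        # planar cis (eclipsed)
        ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)], 0.0),
        # planar trans (anti)
        ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)], 180.0),
        ([(1, 0, 0), (0, 0, 0), (0, 1, 0), (0, 1, 1)], -90.0),
    ],
)
def test_dihedral_reference_geometries(pts, expected):
    assert dihedral_angle(*pts) == pytest.approx(expected, abs=1e-12)


def test_dihedral_matches_rotation_matrix_oracle():
    rng = np.random.default_rng(4)
    for _ in range(300):
        pts = rng.normal(scale=3.0, size=(4, 3))
        got = dihedral_angle(*pts)
        want = _dihedral_rotation_oracle(*pts)
        assert got == pytest.approx(want, abs=1e-9)


def test_dihedral_reversal_invariance_and_mirror_antisymmetry():
    rng = np.random.default_rng(5)
    for _ in range(50):
        pts = rng.normal(size=(4, 3))
        a = dihedral_angle(*pts)
        # a torsion reads the same from either end of the chain
        assert dihedral_angle(*pts[::-1]) == pytest.approx(a, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        b = dihedral_angle(*mirrored)
        if abs(abs(a) - 180.0) > 1e-9 and abs(a) > 1e-9:
            assert b == pytest.approx(-a, abs=1e-9)


def test_dihedral_collinear_raises():
    with pytest.raises(ValueError, match="undefined torsion"):
        dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_dihedral_angles_vectorized_nan_for_collinear():
    p = np.zeros((2, 3))
    p1 = np.array([[0, 1, 0], [0, 0, 0]], float)
    p2 = np.zeros((2, 3))
    p3 = np.array([[1, 0, 0], [1, 0, 0]], float)
    p4 = np.array([[1, -1, 0], [2, 0, 0]], float)
    out = dihedral_angles(p1, p2, p3, p4)
    assert out[0] == pytest.approx(180.0)
    assert np.isnan(out[1])


# --- chain lengths ------------------------------------------------------

def test_chain_lengths_straight_and_folded():
    straight = np.stack([np.arange(16.0), np.zeros(16), np.zeros(16)], axis=1)
    sel = AtomSelection(np.arange(16), np.full(16, 12.011))
    f = frame(straight)
    assert end_to_end_distance(sel, f) == pytest.approx(15.0)
    assert contour_length(sel, f) == pytest.approx(15.0)
    folded = straight.copy()
    folded[-1] = folded[0]
    assert end_to_end_distance(sel, frame(folded)) == pytest.approx(0.0)


@given(st_.integers(min_value=0, max_value=2**32 - 1))
def test_end_to_end_never_exceeds_contour(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    pos = rng.normal(scale=4.0, size=(n, 3))
    sel = AtomSelection(np.arange(n), np.ones(n))
    f = frame(pos)
    e2e = end_to_end_distance(sel, f)
    assert e2e <= contour_length(sel, f) + 1e-12
    assert e2e == pytest.approx(np.linalg.norm(pos[-1] - pos[0]))


def test_chain_length_requires_two_atoms():
    sel = AtomSelection(np.array([0]), np.array([1.0]))
    with pytest.raises(ValueError):
        end_to_end_distance(sel, frame(np.zeros((1, 3))))


# --- data model ---------------------------------------------------------

def test_atom_record_rejects_nonpositive_mass():
    with pytest.raises(ValueError):
        AtomRecord(1, "CA", "GLY", 1, "A", "C", 0.0)


def test_selection_rejects_duplicates():
    with pytest.raises(ValueError):
        AtomSelection(np.array([0, 0]), np.array([1.0, 1.0]))


def test_select_orders_by_declared_name_list():
    top = make_atoms(
        [("C1", "LIP", 700, "A", "C", 12.011),
         ("C3", "LIP", 700, "A", "C", 12.011),
         ("C2", "LIP", 700, "A", "C", 12.011)]
    )
    sel = select(top, names=["C1", "C2", "C3"])
    assert list(sel.resolved_indices) == [0, 2, 1]


def test_mass_lookup():
    assert mass_for_element("C") == pytest.approx(12.011)
    with pytest.raises(KeyError):
        mass_for_element("Xx")
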