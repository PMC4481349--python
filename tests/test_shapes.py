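import numpy as np
import pytest

from lipidgate.geometry import (
    AtomSelection,
    FrameCoordinates,
    Trajectory,
    dihedral_angle,
)
from lipidgate.shapes import (
    FINE_TO_COARSE,
    CoarseShape,
    FineShape,
    ShapeClass,
    ShapeClassificationError,
    ShapeDescriptors,
    TorsionProfile,
    classify_shape,
    compute_shape_descriptors,
    compute_torsion_profile,
    shape_time_series,
)
from lipidgate.synthetic import _build_chain_template, _shape_torsions

from conftest import point_topology, random_rigid_transform


def chain_frame(positions, time=1.0):
    positions = np.asarray(positions, float)
    sel = AtomSelection(np.arange(len(positions)), np.full(len(positions), 12.011))
    return sel, FrameCoordinates(time, positions)


def built_chain(torsions, n_atoms=16):
    return _build_chain_template(np.asarray(torsions, float), n_atoms)


# --- torsion profiles ---------------------------------------------------

def test_all_trans_chain_gives_180_everywhere():
    sel, f = chain_frame(built_chain([180.0] * 13))
    profile = compute_torsion_profile(sel, f)
    assert profile.omegas.shape == (13,)
    assert np.allclose(np.abs(profile.omegas), 180.0, atol=1e-6)


def test_cis_kink_recovered_at_correct_window():
    om = [180.0] * 13
    om[6] = 0.0
    sel, f = chain_frame(built_chain(om))
    profile = compute_torsion_profile(sel, f)
    assert profile.omegas[6] == pytest.approx(0.0, abs=1e-6)
    mask = np.ones(13, bool)
    mask[6] = False
    assert np.allclose(np.abs(profile.omegas[mask]), 180.0, atol=1e-6)


def test_torsion_profile_matches_elementwise_dihedrals():
    rng = np.random.default_rng(20)
    pos = np.cumsum(rng.normal(scale=1.0, size=(10, 3)), axis=0)
    sel, f = chain_frame(pos)
    profile = compute_torsion_profile(sel, f)
    for i in range(len(pos) - 3):
        assert profile.omegas[i] == pytest.approx(
            dihedral_angle(pos[i], pos[i + 1], pos[i + 2], pos[i + 3]), abs=1e-12
        )


def test_collinear_window_flagged_as_missing():
    pos = np.zeros((6, 3))
    pos[:, 0] = np.arange(6)  # fully collinear chain
    sel, f = chain_frame(pos)
    profile = compute_torsion_profile(sel, f)
    assert np.all(np.isnan(profile.omegas))
    assert profile.missing_fraction == 1.0


# --- descriptors --------------------------------------------------------

def test_straight_chain_descriptors():
    pos = np.stack([np.arange(16.0), np.zeros(16), np.zeros(16)], axis=1)
    sel, f = chain_frame(pos)
    d = compute_shape_descriptors(sel, f)
    assert d.r == pytest.approx(1.0)
    assert d.max_bend_deg == pytest.approx(0.0, abs=1e-9)


def test_hairpin_descriptors():
    up = [(0.0, float(i), 0.0) for i in range(8)]
    down = [(1.5, float(7 - i), 0.0) for i in range(8)]
    sel, f = chain_frame(up + down)
    d = compute_shape_descriptors(sel, f)
    assert d.r < 0.15
    assert 0.35 <= d.bend_position <= 0.65
    assert d.max_bend_deg > 150.0


def test_l_shaped_chain_bend_location():
    # 90 degree bend after 4 of 16 atoms (1/4 of the chain)
    arm1 = [(float(i), 0.0, 0.0) for i in range(4)]
    arm2 = [(3.0, float(i + 1), 0.0) for i in range(12)]
    sel, f = chain_frame(arm1 + arm2)
    d = compute_shape_descriptors(sel, f, segment_len=4)
    assert d.max_bend_deg == pytest.approx(90.0, abs=15.0)
    assert d.bend_position == pytest.approx(0.25, abs=0.08)


def test_descriptors_chain_too_short():
    sel, f = chain_frame(np.zeros((5, 3)))
    with pytest.raises(ValueError):
        compute_shape_descriptors(sel, f, segment_len=4)


# --- classification -----------------------------------------------------

def profile_of(omegas):
    return TorsionProfile(0.0, np.asarray(omegas, float))


def test_fine_to_coarse_map_total_and_unique():
    assert set(FINE_TO_COARSE) == set(FineShape) - {FineShape.NA}
    for fine, coarse in FINE_TO_COARSE.items():
        assert isinstance(coarse, CoarseShape)
    with pytest.raises(ValueError):
        ShapeClass(CoarseShape.CURVED, FineShape.EX)


@pytest.mark.parametrize(
    "omegas, fine, coarse",
    [
        ([180.0] * 13, FineShape.EX, CoarseShape.ELONGATED),
        # single isolated non-trans window
        ([180.0] * 6 + [60.0] + [180.0] * 6, FineShape.UEX, CoarseShape.ELONGATED),
        # contiguous gauche block in the first terminal third
        ([180.0, 60.0, 60.0] + [180.0] * 10, FineShape.J, CoarseShape.HOOKED),
        ([180.0, -60.0, -60.0] + [180.0] * 10, FineShape.JP, CoarseShape.HOOKED),
        # central block
        ([180.0] * 5 + [60.0, 60.0, 60.0] + [180.0] * 5, FineShape.U, CoarseShape.CURVED),
        # blocks in both halves
        ([180.0, 60.0, 60.0] + [180.0] * 7 + [60.0, 60.0, 180.0], FineShape.HX, CoarseShape.CURVED),
        ([60.0, 60.0, 180.0, 60.0, 60.0] + [180.0] * 8, FineShape.HXA, CoarseShape.CURVED),
        ([180.0] * 8 + [60.0, 60.0, 180.0, 60.0, 60.0], FineShape.HXB, CoarseShape.CURVED),
    ],
)
def test_torsion_pattern_taxonomy(omegas, fine, coarse):
    sc = classify_shape(profile_of(omegas), None, policy="torsion_pattern")
    assert sc.fine == fine
    assert sc.coarse == coarse


def test_spec_like_terminal_block_is_hooked():
    om = [180.0] * 13
    om[2] = om[3] = 60.0
    sc = classify_shape(profile_of(om), None)
    assert sc.coarse == CoarseShape.HOOKED
    assert sc.fine in (FineShape.J, FineShape.JP)


@pytest.mark.parametrize(
    "r, bend_pos, coarse",
    [
        (1.0, 0.5, CoarseShape.ELONGATED),
        (0.9, 0.2, CoarseShape.ELONGATED),
        (0.5, 0.2, CoarseShape.HOOKED),
        (0.5, 0.8, CoarseShape.HOOKED),
        (0.5, 0.5, CoarseShape.CURVED),
    ],
)
def test_end_to_end_policy(r, bend_pos, coarse):
    d = ShapeDescriptors(r=r, max_bend_deg=90.0, bend_position=bend_pos)
    sc = classify_shape(None, d, policy="end_to_end")
    assert sc.coarse == coarse
    assert sc.fine == FineShape.NA


def test_end_to_end_policy_ignores_torsions():
    d = ShapeDescriptors(r=0.5, max_bend_deg=90.0, bend_position=0.5)
    rng = np.random.default_rng(21)
    base = rng.uniform(-180, 180, size=13)
    for _ in range(5):
        perm = rng.permutation(13)
        sc = classify_shape(profile_of(base[perm]), d, policy="end_to_end")
        assert sc.coarse == CoarseShape.CURVED


def test_classification_refused_on_excess_missing():
    om = np.full(13, 180.0)
    om[:4] = np.nan
    with pytest.raises(ShapeClassificationError):
        classify_shape(profile_of(om), None)


def test_rigid_motion_never_changes_shape_class():
    rng = np.random.default_rng(22)
    for shape in ("elongated", "hooked", "curved"):
        pos = built_chain(_shape_torsions(shape, 13))
        sel, f = chain_frame(pos)
        ref = classify_shape(compute_torsion_profile(sel, f), None)
        for _ in range(20):
            R, t = random_rigid_transform(rng)
            sel2, f2 = chain_frame(pos @ R.T + t)
            got = classify_shape(compute_torsion_profile(sel2, f2), None)
            assert got == ref


# --- time series --------------------------------------------------------

def _traj_from_chains(chains):
    top = point_topology(chains[0].shape[0], resid_start=1)
    frames = [
        FrameCoordinates((i + 1) * 0.01, c) for i, c in enumerate(chains)
    ]
    return Trajectory(top, frames, 0.01), AtomSelection(
        np.arange(chains[0].shape[0]), np.full(chains[0].shape[0], 12.011)
    )


def test_constant_all_trans_trajectory_fully_elongated():
    chain = built_chain([180.0] * 13)
    traj, sel = _traj_from_chains([chain] * 5)
    classes, fractions = shape_time_series(traj, sel)
    assert fractions["elongated"] == pytest.approx(1.0)
    assert all(c.fine == FineShape.EX for c in classes)


def test_empty_trajectory_shape_series():
    chain = built_chain([180.0] * 13)
    traj, sel = _traj_from_chains([chain])
    empty = Trajectory(traj.topology, [], 0.01)
    classes, fractions = shape_time_series(empty, sel)
    assert classes == []
    assert all(v == 0.0 for v in fractions.values())


def test_shape_fractions_recover_generator_emission(synthetic_3k):
    cfg, traj, truth = synthetic_3k
    from lipidgate.geometry import select

    sel = select(traj.topology, chain_id="A", residue_id=700,
                 names=[f"C{i}" for i in range(1, 17)])
    classes, fractions = shape_time_series(traj, sel)
    truth_frac = {
        s: truth.shapes.count(s) / len(truth.shapes)
        for s in ("elongated", "hooked", "curved")
    }
    for s in truth_frac:
        assert fractions[s] == pytest.approx(truth_frac[s], abs=0.03)
    assert fractions["unclassified"] == 0.0
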