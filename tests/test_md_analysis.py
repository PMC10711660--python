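"""Trajectory contact maps, hydrogen bonds and anchoring classification."""

import numpy as np
import pytest

from motifscan.errors import ConfigError, NotFoundError, ValidationError
from motifscan.md_analysis import (
    ContactMap,
    Trajectory,
    average_maps,
    classify_anchored,
    frame_contacts,
    hbond_series,
    in_pocket_fraction,
    load_trajectory,
    marginal_profiles,
    trajectory_contact_map,
    write_trajectory,
)
from motifscan.synthetic import ToyComplexSpec, ToyTrajectorySpec, make_toy_trajectory

from conftest import brute_force_contacts, make_atoms, random_two_chain_atoms


def static_pair_trajectory(distance, n_frames=4):
    rows = [
        ("A", 1, "C1", "C", (0.0, 0.0, 0.0)),
        ("B", 1, "C1", "C", (distance, 0.0, 0.0)),
    ]
    atoms = make_atoms(rows)
    coords = np.repeat(atoms.coord[None], n_frames, axis=0)
    return Trajectory(atoms=atoms, coords=coords)


def test_frame_contact_rule_is_inclusive():
    """The MD rule counts pairs 'within' the cutoff: 4.5 Å exactly is a contact."""
    assert len(frame_contacts(static_pair_trajectory(4.5), 0)) == 1
    assert len(frame_contacts(static_pair_trajectory(4.6), 0)) == 0


@pytest.mark.parametrize("seed", range(6))
def test_frame_contacts_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    atoms = random_two_chain_atoms(rng)
    coords = np.repeat(atoms.coord[None], 2, axis=0)
    coords[1] += rng.normal(0, 1.5, coords[1].shape)
    traj = Trajectory(atoms=atoms, coords=coords)
    for f in range(2):
        shifted = atoms.copy()
        shifted.coord = coords[f].astype(np.float32)
        # oracle works on residue positions, matching the frame's pair labels
        want = brute_force_contacts(shifted, 4.5, heavy_only=True, inclusive=True)
        got = {
            (int(np.nonzero(traj.chain_residues("A") == i)[0][0]) + 1,
             int(np.nonzero(traj.chain_residues("B") == j)[0][0]) + 1)
            for i, j in frame_contacts(traj, f, 4.5).pairs
        }
        assert got == want


def test_frame_contacts_cross_checked_against_mdanalysis(tmp_path):
    """Independent route: MDAnalysis distance arrays on the written file."""
    MDAnalysis = pytest.importorskip("MDAnalysis")
    from MDAnalysis.lib.distances import distance_array

    spec = ToyTrajectorySpec(
        complex=ToyComplexSpec(8, 5, planted_pairs=((2, 3), (6, 5))),
        n_frames=3, jitter_sigma=0.3, seed=4,
    )
    traj = make_toy_trajectory(spec)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    u = MDAnalysis.Universe(str(path))
    bait = u.select_atoms("segid A or chainID A")
    prey = u.select_atoms("segid B or chainID B")
    for f, ts in enumerate(u.trajectory):
        d = distance_array(bait.positions, prey.positions)
        want = set()
        for (i, j) in zip(*np.nonzero(d <= 4.5)):
            want.add((int(bait.resids[i]), int(prey.resids[j])))
        assert frame_contacts(traj, f, 4.5).pairs == want


def test_static_trajectory_map_is_binary_indicator():
    traj = static_pair_trajectory(4.0, n_frames=5)
    cmap = trajectory_contact_map(traj)
    single = frame_contacts(traj, 0)
    assert cmap.freq[0, 0] == 1.0
    assert (1, 1) in single.pairs


def test_bound_fraction_sets_planted_pair_frequency():
    spec = ToyTrajectorySpec(
        complex=ToyComplexSpec(6, 4, planted_pairs=((2, 2),)),
        n_frames=10, bound_fraction=0.5, jitter_sigma=0.0,
    )
    cmap = trajectory_contact_map(make_toy_trajectory(spec))
    assert cmap.frequency(2, 2) == pytest.approx(0.5)


def test_one_frame_trajectory_gives_binary_map():
    spec = ToyTrajectorySpec(complex=ToyComplexSpec(4, 3, planted_pairs=((1, 1),)), n_frames=1)
    cmap = trajectory_contact_map(make_toy_trajectory(spec))
    assert set(np.unique(cmap.freq)) <= {0.0, 1.0}


def test_concatenation_equals_frame_weighted_mean():
    spec_a = ToyTrajectorySpec(
        complex=ToyComplexSpec(5, 3, planted_pairs=((2, 1),)), n_frames=4, bound_fraction=1.0
    )
    spec_b = ToyTrajectorySpec(
        complex=ToyComplexSpec(5, 3, planted_pairs=((2, 1),)), n_frames=12, bound_fraction=0.0
    )
    ta, tb = make_toy_trajectory(spec_a), make_toy_trajectory(spec_b)
    combined = Trajectory(atoms=ta.atoms, coords=np.concatenate([ta.coords, tb.coords]))
    ma, mb, mc = (trajectory_contact_map(t) for t in (ta, tb, combined))
    weighted = (ma.freq * 4 + mb.freq * 12) / 16
    assert np.allclose(mc.freq, weighted)


def test_average_maps_is_mean_and_idempotent():
    axes = dict(bait_axis=np.array([1]), prey_axis=np.array([1]))
    m1 = ContactMap(freq=np.array([[1.0]]), n_frames=10, **axes)
    m0 = ContactMap(freq=np.array([[0.0]]), n_frames=10, **axes)
    avg = average_maps([m1, m0])
    assert avg.freq[0, 0] == 0.5
    assert avg.n_replicates == 2
    same = average_maps([m1] * 10)
    assert same.freq[0, 0] == 1.0

    fractions = np.round(np.arange(0.1, 1.01, 0.1), 2)
    maps = [ContactMap(freq=np.array([[f]]), n_frames=10, **axes) for f in fractions]
    assert average_maps(maps).freq[0, 0] == pytest.approx(0.55)


def test_average_maps_permutation_invariant_and_axis_checked():
    rng = np.random.default_rng(3)
    axes = dict(bait_axis=np.array([1, 2]), prey_axis=np.array([1, 2, 3]))
    maps = [ContactMap(freq=rng.random((2, 3)), n_frames=5, **axes) for _ in range(6)]
    a = average_maps(maps)
    b = average_maps(maps[::-1])
    assert np.allclose(a.freq, b.freq)
    other = ContactMap(
        bait_axis=np.array([1, 3]), prey_axis=np.array([1, 2, 3]),
        freq=np.zeros((2, 3)), n_frames=5,
    )
    with pytest.raises(ValidationError):
        average_maps([maps[0], other])


def test_marginal_profiles_worked_example():
    """Map rows are prey residues: [[1,0],[0.5,0.5]] gives prey sums (1,1)
    and bait sums (1.5, 0.5)."""
    prey_rows = np.array([[1.0, 0.0], [0.5, 0.5]])
    cmap = ContactMap(
        bait_axis=np.array([1, 2]), prey_axis=np.array([1, 2]),
        freq=prey_rows.T, n_frames=1,
    )
    bait_profile, prey_profile = marginal_profiles(cmap)
    assert prey_profile.tolist() == [1.0, 1.0]
    assert bait_profile.tolist() == [1.5, 0.5]
    assert bait_profile.sum() == pytest.approx(prey_profile.sum())
    assert bait_profile.sum() == pytest.approx(cmap.freq.sum())


def test_marginals_of_zero_and_single_pair_maps():
    zero = ContactMap(np.array([1, 2]), np.array([1]), np.zeros((2, 1)), 1)
    bp, pp = marginal_profiles(zero)
    assert bp.sum() == pp.sum() == 0.0
    single = ContactMap(np.array([1]), np.array([1]), np.array([[0.7]]), 1)
    bp, pp = marginal_profiles(single)
    assert bp.tolist() == [0.7] and pp.tolist() == [0.7]


def hbond_trajectory(da_dists, angle_deg=165.0):
    """Donor on A, hydrogen bonded to donor, acceptor on B placed per frame."""
    rows = [
        ("A", 1, "OG", "O", (0.0, 0.0, 0.0)),
        ("A", 1, "HG", "H", (1.0, 0.0, 0.0)),
        ("B", 1, "O", "O", (2.0, 0.0, 0.0)),
    ]
    atoms = make_atoms(rows)
    coords = np.repeat(atoms.coord[None].astype(float), len(da_dists), axis=0)
    theta = np.radians(180.0 - angle_deg)
    for f, d in enumerate(da_dists):
        # acceptor at D-A distance d such that the D-H-A angle is angle_deg
        ax = 1.0 + (d - 1.0) * np.cos(theta)
        ay = (d - 1.0) * np.sin(theta)
        # adjust: place acceptor relative to H at distance giving D-A = d
        coords[f, 2] = (ax, ay, 0.0)
    return Trajectory(atoms=atoms, coords=coords)


def test_hbond_engaged_when_close_and_straight():
    traj = hbond_trajectory([2.9, 2.9], angle_deg=165.0)
    series = hbond_series(traj, ("A", 1, "OG"), ("B", 1, "O"), hydrogen=("A", 1, "HG"))
    assert series.persistence == 1.0
    assert np.all(series.angles > 150.0)


def test_hbond_distance_gate():
    traj = hbond_trajectory([4.0, 4.0])
    series = hbond_series(traj, ("A", 1, "OG"), ("B", 1, "O"))
    assert series.persistence == 0.0
    assert np.allclose(series.distances, 4.0, atol=0.05)


def test_hbond_angle_gate():
    traj = hbond_trajectory([2.9, 2.9], angle_deg=120.0)
    series = hbond_series(traj, ("A", 1, "OG"), ("B", 1, "O"), hydrogen=("A", 1, "HG"))
    assert series.persistence == 0.0
    # distance-only fallback ignores the bent geometry
    no_h = hbond_series(traj, ("A", 1, "OG"), ("B", 1, "O"))
    assert no_h.persistence == 1.0


def test_hbond_alternating_frames_give_half_persistence():
    traj = hbond_trajectory([2.9, 6.0, 2.9, 6.0])
    series = hbond_series(traj, ("A", 1, "OG"), ("B", 1, "O"))
    assert series.persistence == 0.5
    assert series.distances[0] == pytest.approx(2.9, abs=0.05)
    assert series.distances[1] == pytest.approx(6.0, abs=0.05)


def test_hbond_unknown_atom_raises():
    traj = hbond_trajectory([2.9])
    with pytest.raises(NotFoundError):
        hbond_series(traj, ("A", 1, "XX"), ("B", 1, "O"))


BASE = ToyComplexSpec(bait_length=8, prey_length=5, planted_pairs=((3, 4), (5, 4)))


def test_fully_bound_replicate_is_anchored():
    traj = make_toy_trajectory(ToyTrajectorySpec(complex=BASE, n_frames=20))
    assert in_pocket_fraction(traj, 4, [3, 5]) == 1.0


def test_midpoint_unbinding_gives_half_fraction_and_anchored_call():
    traj = make_toy_trajectory(
        ToyTrajectorySpec(complex=BASE, n_frames=20, unbinding_frame=10)
    )
    result = classify_anchored([traj], 4, [3, 5], frame_fraction_threshold=0.5)
    assert result.fractions == [0.5]
    assert result.anchored == [True]


def test_nine_of_ten_replicates_anchored():
    trajs = [
        make_toy_trajectory(
            ToyTrajectorySpec(complex=BASE, n_frames=20, bound_fraction=1.0,
                              jitter_sigma=0.05, seed=s)
        )
        for s in range(9)
    ]
    trajs.append(
        make_toy_trajectory(
            ToyTrajectorySpec(complex=BASE, n_frames=20, bound_fraction=0.0,
                              jitter_sigma=0.05, seed=19)
        )
    )
    result = classify_anchored(trajs, 4, [3, 5])
    assert result.n_anchored == 9
    assert result.n_replicates == 10


def test_residue_without_side_chain_cannot_be_classified():
    rows = [
        ("A", 1, "C1", "C", (0.0, 0.0, 0.0)),
        ("B", 1, "CA", "C", (4.0, 0.0, 0.0)),  # backbone only
    ]
    atoms = make_atoms(rows)
    traj = Trajectory(atoms=atoms, coords=atoms.coord[None])
    with pytest.raises(ConfigError):
        in_pocket_fraction(traj, 1, [1])


def test_trajectory_pdb_round_trip(tmp_path):
    spec = ToyTrajectorySpec(
        complex=ToyComplexSpec(6, 4, planted_pairs=((2, 2),)),
        n_frames=5, bound_fraction=0.6, jitter_sigma=0.2, seed=8,
    )
    traj = make_toy_trajectory(spec)
    path = tmp_path / "t.pdb"
    write_trajectory(traj, path)
    again = load_trajectory(path)
    assert again.n_frames == 5
    assert np.allclose(
        trajectory_contact_map(traj).freq, trajectory_contact_map(again).freq
    )
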