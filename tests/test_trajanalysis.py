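import numpy as np
import pytest
from dataclasses import replace
from scipy.spatial.transform import Rotation

from nmrscore import structio, synthgen, trajanalysis
from nmrscore.errors import DataError

from conftest import build_structure


def make_traj(structure, frames):
    stack = np.stack(frames)
    return trajanalysis.Trajectory(structure=replace(structure, coords=stack))


@pytest.fixture
def jittered(small_complex):
    s, truth = small_complex
    return synthgen.make_trajectory(s, truth, n_frames=8, jitter_sigma=0.05,
                                    seed=11)


class TestReadTrajectory:
    def test_multimodel(self, tmp_path, jittered):
        traj, _ = jittered
        path = tmp_path / "t.pdb"
        structio.write_structure(traj.structure, path)
        back = trajanalysis.read_trajectory(path)
        assert back.n_frames == 8

    def test_frame_directory_name_order(self, tmp_path, small_complex):
        s, truth = small_complex
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=3, seed=0,
                                           jitter_sigma=0.3)
        for f in range(1, 4):
            single = replace(s, coords=traj.frame(f)[np.newaxis])
            structio.write_structure(single, tmp_path / f"frame_{f:03d}.pdb")
        back = trajanalysis.read_trajectory(tmp_path)
        assert back.n_frames == 3
        for f in range(1, 4):
            assert np.allclose(back.frame(f), traj.frame(f), atol=1e-3)

    def test_mismatched_frame_named(self, tmp_path, small_complex):
        s, truth = small_complex
        structio.write_structure(s, tmp_path / "a_frame1.pdb")
        smaller = structio.select(s, "heavy")
        sub = replace(
            s,
            chain_ids=s.chain_ids[smaller.indices],
            res_nums=s.res_nums[smaller.indices],
            icodes=s.icodes[smaller.indices],
            res_names=s.res_names[smaller.indices],
            atom_names=s.atom_names[smaller.indices],
            elements=s.elements[smaller.indices],
            serials=s.serials[smaller.indices],
            hetero=s.hetero[smaller.indices],
            coords=s.coords[:, smaller.indices],
        )
        structio.write_structure(sub, tmp_path / "b_frame2.pdb")
        with pytest.raises(DataError, match="frame 2"):
            trajanalysis.read_trajectory(tmp_path)


class TestContactFrequency:
    def test_static_all_or_nothing(self, small_complex):
        s, truth = small_complex
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=4,
                                           jitter_sigma=0.0, seed=0)
        cmap = trajanalysis.contact_frequency(traj, ["A"], ["B"])
        assert set(cmap.frequencies.values()) == {100.0}
        got_pairs = {(a[1], b[1]) for a, b in cmap.frequencies}
        assert got_pairs == set(truth.contacts)

    def test_partial_contact_fraction(self, small_complex):
        s, truth = small_complex
        # escape at frame 4 of 4: contacts in frames 1-3 -> 75%
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=4,
                                           jitter_sigma=0.0, escape_at=4, seed=0)
        cmap = trajanalysis.contact_frequency(traj, ["A"], ["B"])
        assert set(cmap.frequencies.values()) == {75.0}

    def test_per_frame_bruteforce_oracle(self, jittered):
        traj, _ = jittered
        cmap = trajanalysis.contact_frequency(traj, ["A"], ["B"], cutoff=5.0)
        s = traj.structure
        mask_a = np.flatnonzero(s.chain_ids == "A")
        mask_b = np.flatnonzero(s.chain_ids == "B")
        oracle: dict = {}
        for f in range(1, traj.n_frames + 1):
            c = traj.frame(f)
            seen = set()
            for i in mask_a:
                for j in mask_b:
                    if np.linalg.norm(c[i] - c[j]) <= 5.0:
                        seen.add((("A", int(s.res_nums[i])),
                                  ("B", int(s.res_nums[j]))))
            for k in seen:
                oracle[k] = oracle.get(k, 0) + 1
        oracle = {k: 100.0 * v / traj.n_frames for k, v in oracle.items()}
        assert cmap.frequencies == pytest.approx(oracle)

    def test_window_restriction_gives_100(self, small_complex):
        s, truth = small_complex
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=10,
                                           jitter_sigma=0.0, escape_at=6, seed=0)
        cmap = trajanalysis.contact_frequency(traj, ["A"], ["B"], window=(1, 5))
        assert set(cmap.frequencies.values()) == {100.0}

    def test_empty_window_rejected(self, jittered):
        traj, _ = jittered
        with pytest.raises(DataError):
            trajanalysis.contact_frequency(traj, ["A"], ["B"], window=(5, 99))


def hbond_fixture(da=2.9, deviation_deg=0.0):
    """Donor N-H on chain B pointing at acceptor O on chain A.

    The acceptor sits along a direction making exactly ``deviation_deg`` with
    the extended N-H axis at H, at the H-A distance that yields a donor-
    acceptor separation of ``da``.
    """
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([0.0, -1.0, 0.0])
    delta = np.radians(deviation_deg)
    # direction from H deviating by delta from the continued N->H direction
    u = np.array([0.0, -np.cos(delta), np.sin(delta)])
    # |n - (h + r u)| = da  =>  r^2 + 2 r cos(delta) + 1 - da^2 = 0
    r = -np.cos(delta) + np.sqrt(np.cos(delta) ** 2 - 1.0 + da ** 2)
    acc = h + r * u
    assert np.linalg.norm(acc - n) == pytest.approx(da, abs=1e-12)
    rows = [("B", 1, "ALA", "N", "N", tuple(n)),
            ("B", 1, "ALA", "H", "H", tuple(h)),
            ("A", 1, "ALA", "O", "O", tuple(acc))]
    return build_structure(rows)


class TestHbonds:
    def run(self, s, **kwargs):
        traj = make_traj(s, [s.conformer_coords(1)] * 2)
        return trajanalysis.hbonds(traj, ["A"], ["B"], **kwargs)

    def test_ideal_geometry_detected(self):
        records = self.run(hbond_fixture(2.9, 0.0))
        assert len(records) == 1
        assert records[0].frequency == 100.0
        assert records[0].mean_distance == pytest.approx(2.9, abs=1e-6)
        assert records[0].mean_deviation == pytest.approx(0.0, abs=1e-6)

    def test_30_degree_deviation_rejected(self):
        assert self.run(hbond_fixture(2.9, 30.0)) == []

    def test_boundary_exactly_at_cutoffs_detected(self):
        assert len(self.run(hbond_fixture(3.0, 0.0))) == 1
        records = self.run(hbond_fixture(2.9, 19.99))
        assert len(records) == 1
        assert records[0].mean_deviation == pytest.approx(19.99, abs=0.01)

    def test_just_past_cutoffs_rejected(self):
        assert self.run(hbond_fixture(3.01, 0.0)) == []
        assert self.run(hbond_fixture(2.9, 20.5)) == []

    def test_loosening_cutoffs_monotone(self):
        s = hbond_fixture(2.95, 15.0)
        tight = self.run(s, d_cut=3.0, ang_cut=20.0)
        loose_d = self.run(s, d_cut=3.5, ang_cut=20.0)
        loose_a = self.run(s, d_cut=3.0, ang_cut=35.0)
        keys = lambda rs: {(r.donor, r.hydrogen, r.acceptor) for r in rs}
        assert keys(tight) <= keys(loose_d)
        assert keys(tight) <= keys(loose_a)

    def test_requires_hydrogens(self, small_complex):
        s, _ = small_complex
        heavy = structio.select(s, "heavy")
        sub = replace(
            s,
            chain_ids=s.chain_ids[heavy.indices],
            res_nums=s.res_nums[heavy.indices],
            icodes=s.icodes[heavy.indices],
            res_names=s.res_names[heavy.indices],
            atom_names=s.atom_names[heavy.indices],
            elements=s.elements[heavy.indices],
            serials=s.serials[heavy.indices],
            hetero=s.hetero[heavy.indices],
            coords=s.coords[:, heavy.indices],
        )
        with pytest.raises(DataError, match="hydrogens"):
            trajanalysis.hbonds(trajanalysis.Trajectory(structure=sub),
                                ["A"], ["B"])

    def test_planted_persistence_fraction(self, small_complex):
        s, truth = small_complex
        # escape at frame 9 of 10 -> planted H-bonds live in 8/10 frames
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=10,
                                           jitter_sigma=0.0, escape_at=9, seed=0)
        records = trajanalysis.hbonds(traj, ["A"], ["B"])
        assert len(records) == len(truth.hbonds)
        for r in records:
            assert r.frequency == pytest.approx(80.0)


class TestLigandRmsd:
    def test_rigid_copies_zero(self, small_complex):
        s, truth = small_complex
        base = s.conformer_coords(1)
        rng = np.random.default_rng(0)
        frames = [base]
        for _ in range(3):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.uniform(-5, 5, 3))
        traj = make_traj(s, frames)
        values, mean = trajanalysis.ligand_rmsd_series(
            traj, "chain A and backbone", "chain B and backbone")
        assert np.all(values < 1e-6)
        assert mean < 1e-6

    def test_translated_ligand_analytic(self, small_complex):
        s, _ = small_complex
        base = s.conformer_coords(1)
        shifted = base.copy()
        mask = s.chain_ids == "B"
        # translate ligand 5 A along an arbitrary unit vector in the global frame
        shifted[mask] += np.array([3.0, 4.0, 0.0]) * (5.0 / 5.0)
        traj = make_traj(s, [base, shifted])
        values, _ = trajanalysis.ligand_rmsd_series(
            traj, "chain A and backbone", "chain B and backbone")
        assert values[0] == pytest.approx(0.0, abs=1e-9)
        assert values[1] == pytest.approx(5.0, abs=1e-6)

    def test_global_rigid_transform_invariance(self, jittered):
        traj, _ = jittered
        values, _ = trajanalysis.ligand_rmsd_series(
            traj, "chain A and backbone", "chain B and backbone")
        rng = np.random.default_rng(1)
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-10, 10, 3)
        moved = make_traj(traj.structure, list(traj.structure.coords @ rot.T + trans))
        values2, _ = trajanalysis.ligand_rmsd_series(
            moved, "chain A and backbone", "chain B and backbone")
        assert np.allclose(values, values2, atol=1e-6)

    def test_jitter_expectation_oracle(self):
        # ~200 ligand atoms; reference frame unjittered, others with sigma
        s, truth = synthgen.make_complex(40, 34, 10, seed=9)
        sigma = 0.3
        base = s.conformer_coords(1)
        rng = np.random.default_rng(2)
        frames = [base]
        mask = s.chain_ids == "B"
        for _ in range(20):
            f = base.copy()
            f[mask] += rng.normal(0, sigma, size=(mask.sum(), 3))
            frames.append(f)
        traj = make_traj(s, frames)
        values, _ = trajanalysis.ligand_rmsd_series(
            traj, "chain A and backbone", "chain B")
        # E[RMSD] ~ sqrt(3) sigma for i.i.d. per-atom jitter
        assert np.mean(values[1:]) == pytest.approx(np.sqrt(3) * sigma, rel=0.1)

    def test_tail_exclusion(self, small_complex):
        s, _ = small_complex
        base = s.conformer_coords(1)
        shifted = base.copy()
        # move only ligand residues 9-10 ("tails")
        mask = (s.chain_ids == "B") & (s.res_nums >= 9)
        shifted[mask] += 50.0
        traj = make_traj(s, [base, shifted])
        values, _ = trajanalysis.ligand_rmsd_series(
            traj, "chain A and backbone", "chain B and backbone",
            exclude=[(9, 10)])
        assert values[1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_after_exclusion(self, small_complex):
        s, _ = small_complex
        traj = make_traj(s, [s.conformer_coords(1)] * 2)
        with pytest.raises(DataError):
            trajanalysis.ligand_rmsd_series(
                traj, "chain A", "chain B", exclude=[(1, 10)])


class TestClusterFrames:
    def test_two_pose_groups(self, small_complex):
        s, truth = small_complex
        base = s.conformer_coords(1)
        rng = np.random.default_rng(3)
        mask = s.chain_ids == "B"
        frames = []
        for i in range(10):
            f = base + rng.normal(0, 0.05, size=base.shape)
            if i >= 7:  # minority pose: ligand displaced
                f[mask] += np.array([0.0, 0.0, 15.0])
            frames.append(f)
        traj = make_traj(s, frames)
        result = trajanalysis.cluster_frames(
            traj, "chain B", threshold=3.0, align_sel="chain A")
        assert result.representative_frame <= 7
        assert max(result.cluster_sizes.values()) == 7
        labels = result.labels
        assert len(set(labels[:7])) == 1 and len(set(labels[7:])) == 1
        assert labels[0] != labels[9]

    def test_identical_frames_single_cluster(self, small_complex):
        s, _ = small_complex
        traj = make_traj(s, [s.conformer_coords(1)] * 5)
        result = trajanalysis.cluster_frames(traj, "chain B", threshold=1.0)
        assert len(result.cluster_sizes) == 1
        assert result.representative_frame == 1

    def test_tiny_threshold_singletons_lowest_index(self, small_complex):
        s, truth = small_complex
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=5,
                                           jitter_sigma=0.5, seed=4)
        result = trajanalysis.cluster_frames(traj, "chain B", threshold=1e-6)
        assert len(result.cluster_sizes) == 5
        assert result.representative_frame == 1

    def test_permuted_frames_same_clusters_as_sets(self, small_complex):
        s, truth = small_complex
        traj, _ = synthgen.make_trajectory(s, truth, n_frames=6,
                                           jitter_sigma=0.3, seed=5)
        result = trajanalysis.cluster_frames(traj, "chain B", threshold=2.0,
                                             align_sel="chain A")
        perm = [3, 1, 5, 2, 6, 4]
        permuted = make_traj(s, [traj.frame(f) for f in perm])
        result2 = trajanalysis.cluster_frames(permuted, "chain B", threshold=2.0,
                                              align_sel="chain A")

        def cluster_sets(labels, order):
            groups = {}
            for pos, lab in enumerate(labels):
                groups.setdefault(lab, set()).add(order[pos])
            return {frozenset(v) for v in groups.values()}

        assert cluster_sets(result.labels, list(range(1, 7))) == \
            cluster_sets(result2.labels, perm)

    def test_bad_threshold(self, small_complex):
        s, _ = small_complex
        traj = make_traj(s, [s.conformer_coords(1)] * 3)
        with pytest.raises(DataError):
            trajanalysis.cluster_frames(traj, "chain B", threshold=0.0)
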