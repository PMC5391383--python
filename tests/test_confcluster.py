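"""Kabsch RMSD, single-linkage clustering and medoid extraction.

The superposition is cross-checked two independent ways: a coarse-to-fine
grid search over rotations, and MDAnalysis' reference implementation.
Clustering is checked against a literal transitive-closure oracle.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tailscope.confcluster import (
    Clustering,
    RMSDMatrix,
    kabsch_rmsd,
    representative,
    rmsd_matrix,
    single_linkage,
)
from tailscope.errors import SelectionError
from tailscope.structio import Trajectory
from tailscope.synthdata import PeptideGenSpec, gen_peptide_trajectory


def grid_search_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Coarse-to-fine rotation scan: independent of the SVD route."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_for(rots):
        moved = np.einsum("rij,nj->rni", rots.as_matrix(), a)
        return np.sqrt(((moved - b) ** 2).sum(axis=(1, 2)) / len(a))

    # global 20-degree Euler scan
    grid = np.stack(np.meshgrid(
        np.arange(-180, 180, 20), np.arange(-90, 91, 20), np.arange(-180, 180, 20),
        indexing="ij"), axis=-1).reshape(-1, 3)
    rots = Rotation.from_euler("zyx", grid, degrees=True)
    vals = rmsd_for(rots)
    best_rot = rots[int(np.argmin(vals))]
    best_val = float(vals.min())
    # stochastic local refinement in rotation space (no Euler singularities)
    rng = np.random.default_rng(0)
    for scale_deg in (10.0, 2.0, 0.4, 0.08):
        for _ in range(3):
            vecs = rng.normal(size=(400, 3))
            vecs *= (rng.uniform(0, np.radians(scale_deg), size=(400, 1))
                     / np.linalg.norm(vecs, axis=1, keepdims=True))
            cand = Rotation.from_rotvec(vecs) * best_rot
            vals = rmsd_for(cand)
            k = int(np.argmin(vals))
            if vals[k] < best_val:
                best_val = float(vals[k])
                best_rot = cand[k]
    return best_val


class TestKabschRMSD:
    def test_identical_sets_give_zero(self):
        a = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        r = Rotation.random(random_state=2).as_matrix()
        b = a @ r.T + np.array([5.0, -3.0, 11.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_matches_rotation_grid_oracle_on_4_points(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 3)) * 3.0
        b = rng.normal(size=(4, 3)) * 3.0
        assert kabsch_rmsd(a, b) == pytest.approx(grid_search_rmsd(a, b), abs=1e-3)

    def test_matches_mdanalysis_reference(self):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(4)
        a = rng.normal(size=(15, 3)) * 4.0
        b = rng.normal(size=(15, 3)) * 4.0
        ref = mda_rms.rmsd(a, b, center=True, superposition=True)
        assert kabsch_rmsd(a, b) == pytest.approx(ref, abs=1e-6)

    def test_few_points_warns(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.warns(UserWarning):
            kabsch_rmsd(a, a + 1.0)

    def test_collinear_warns(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            kabsch_rmsd(a, a[::-1])


@pytest.fixture(scope="module")
def traj():
    return gen_peptide_trajectory(PeptideGenSpec(seed=9, n_res=20, n_frames=6))


class TestRMSDMatrix:
    def test_two_frame_matrix_matches_direct_call(self, traj):
        two = Trajectory(traj.topology, traj.frames[:2], traj.dt)
        m = rmsd_matrix(two)
        ca = traj.topology.ca_indices()
        direct = kabsch_rmsd(traj.frames[0][ca], traj.frames[1][ca])
        assert m.values[0, 1] == pytest.approx(direct, abs=1e-9)
        assert m.values[1, 0] == m.values[0, 1]

    def test_constant_trajectory_all_zero(self, traj):
        const = Trajectory(traj.topology, np.repeat(traj.frames[:1], 4, axis=0), traj.dt)
        assert np.allclose(rmsd_matrix(const).values, 0.0)

    def test_tip_selection_ignores_downstream_motion(self):
        base = gen_peptide_trajectory(PeptideGenSpec(seed=10, n_res=30, n_frames=1))
        f0 = base.frames[0]
        f1 = f0.copy()
        ca = base.topology.ca_indices((16, 30))
        f1[min(a for a in ca):] += np.array([0.0, 0.0, 7.0])  # move only the tail end
        traj = Trajectory(base.topology, np.stack([f0, f1]), base.dt)
        tip = rmsd_matrix(traj, selection=(1, 15))
        full = rmsd_matrix(traj, selection=(1, 30))
        assert tip.values[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert full.values[0, 1] > 0.5

    def test_missing_selection(self, traj):
        with pytest.raises(SelectionError):
            rmsd_matrix(traj, selection=(100, 120))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            RMSDMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))


def closure_clusters(values: np.ndarray, cutoff: float) -> list[set[int]]:
    """Transitive closure over pairs with distance <= cutoff (literal BFS)."""
    n = values.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            i = queue.pop()
            for j in range(n):
                if j not in comp and values[i, j] <= cutoff:
                    comp.add(j)
                    queue.append(j)
        seen |= comp
        comps.append(comp)
    return comps


def random_rmsd_like(rng, n):
    d = rng.uniform(0, 20, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return RMSDMatrix(d)


class TestSingleLinkage:
    def test_all_close_gives_one_cluster(self):
        m = random_rmsd_like(np.random.default_rng(0), 12)
        c = single_linkage(m, cutoff=25.0)
        assert c.n_clusters == 1
        assert (c.assignment == 0).all()

    def test_block_matrix_recovers_blocks(self):
        n1, n2 = 4, 3
        v = np.full((n1 + n2, n1 + n2), 30.0)
        v[:n1, :n1] = 2.0
        v[n1:, n1:] = 2.0
        np.fill_diagonal(v, 0.0)
        c = single_linkage(RMSDMatrix(v), cutoff=13.0)
        assert c.n_clusters == 2
        assert set(c.members(0)) == set(range(n1))  # larger block ranked first
        assert set(c.members(1)) == set(range(n1, n1 + n2))

    def test_zero_cutoff_gives_singletons(self):
        m = random_rmsd_like(np.random.default_rng(1), 8)
        c = single_linkage(m, cutoff=0.0)
        assert c.n_clusters == 8
        assert c.populations() == [1] * 8

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        m = random_rmsd_like(rng, n)
        cutoff = float(rng.uniform(2, 15))
        c = single_linkage(m, cutoff)
        expected = {frozenset(comp) for comp in closure_clusters(m.values, cutoff)}
        got = {frozenset(map(int, c.members(k))) for k in range(c.n_clusters)}
        assert got == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_cluster_count_monotone_in_cutoff(self, seed):
        m = random_rmsd_like(np.random.default_rng(100 + seed), 30)
        counts = [single_linkage(m, c).n_clusters for c in np.linspace(0, 22, 12)]
        assert counts == sorted(counts, reverse=True)

    def test_invariant_under_frame_permutation(self):
        rng = np.random.default_rng(7)
        m = random_rmsd_like(rng, 20)
        perm = rng.permutation(20)
        mp = RMSDMatrix(m.values[np.ix_(perm, perm)])
        a = single_linkage(m, 8.0)
        b = single_linkage(mp, 8.0)
        parts_a = {frozenset(map(int, a.members(k))) for k in range(a.n_clusters)}
        parts_b = {
            frozenset(int(perm[i]) for i in b.members(k)) for k in range(b.n_clusters)
        }
        assert parts_a == parts_b

    def test_population_tie_broken_by_lowest_frame(self):
        v = np.full((4, 4), 30.0)
        v[0, 1] = v[1, 0] = 1.0
        v[2, 3] = v[3, 2] = 1.0
        np.fill_diagonal(v, 0.0)
        c = single_linkage(RMSDMatrix(v), cutoff=5.0)
        assert set(c.members(0)) == {0, 1}


class TestRepresentative:
    def test_single_frame_trajectory(self):
        traj = gen_peptide_trajectory(PeptideGenSpec(seed=12, n_res=10, n_frames=1))
        c = single_linkage(rmsd_matrix(traj), cutoff=13.0)
        rep = representative(traj, c, k=1)
        np.testing.assert_allclose(rep.coords, traj.frames[0])

    def test_two_block_medoid_matches_exhaustive_scan(self):
        traj = gen_peptide_trajectory(PeptideGenSpec(seed=13, n_res=12, n_frames=9))
        # make the minority block conformationally distinct (translation alone
        # would be removed by the superposition)
        frames = traj.frames.copy()
        frames[5:] = (frames[5:] - frames[5:].mean(axis=1, keepdims=True)) * 5.0
        traj = Trajectory(traj.topology, frames, traj.dt)
        m = rmsd_matrix(traj)
        c = single_linkage(m, cutoff=13.0)
        assert c.n_clusters == 2
        big = c.members(0)
        assert set(big) == set(range(5))
        sums = m.values[np.ix_(big, big)].sum(axis=1)
        expect = int(big[int(np.argmin(sums))])
        rep = representative(traj, c, k=1)
        np.testing.assert_allclose(rep.coords, frames[expect])
        assert f"frame {expect}" in rep.label

    def test_rank_out_of_range(self):
        traj = gen_peptide_trajectory(PeptideGenSpec(seed=12, n_res=10, n_frames=2))
        c = single_linkage(rmsd_matrix(traj), cutoff=100.0)
        with pytest.raises(SelectionError):
            representative(traj, c, k=2)

    def test_full_then_tip_reclustering_pipeline(self):
        """13-Å full-tail clustering then tip re-clustering, end to end."""
        traj = gen_peptide_trajectory(PeptideGenSpec(seed=14, n_frames=25))
        full = single_linkage(rmsd_matrix(traj, selection=(1, 43)), cutoff=13.0)
        tips = single_linkage(rmsd_matrix(traj, selection=(1, 15)), cutoff=13.0)
        for c in (full, tips):
            assert c.assignment.shape == (25,)
            for k in range(c.n_clusters):
                assert c.medoids[k] in c.members(k)
        rep = representative(traj, full, k=1)
        assert len(rep.residues()) == 43
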