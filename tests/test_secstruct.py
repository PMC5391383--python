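"""Hydrogen-bond detection and secondary-structure assignment.

The independent oracle reimplements the electrostatic H-bond energy and the
pattern rules as literal nested loops, so any vectorization slip in the
module shows up as a disagreement.
"""

import numpy as np
import pytest

from tailscope.errors import AssignmentError
from tailscope.secstruct import (
    SSParams,
    SS_CODES,
    assign_ss,
    backbone_hbonds,
    occupancy,
    ss_matrix,
)
from tailscope.structio import Structure, Trajectory
from tailscope.synthdata import PeptideGenSpec, Segment, gen_peptide_trajectory


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def oracle_hbonds(frame, topology, params=SSParams()):
    """Literal all-pairs evaluation of the H-bond energy with rebuilt amide H."""
    res = topology.residues()
    res_ids = [r for _, r, _ in res]
    res_names = [n for _, _, n in res]
    pos = {(a.res_seq, a.name): np.array(a.coords) for a in topology.atoms}
    xyz = np.asarray(frame)
    idx = {(a.res_seq, a.name): i for i, a in enumerate(topology.atoms)}

    def at(r, name):
        return xyz[idx[(r, name)]]

    bonds = []
    for i, ri in enumerate(res_ids):
        if res_names[i] == "PRO":
            continue
        if (ri, "H") in idx:
            h = at(ri, "H")
        elif i > 0:
            v = at(res_ids[i - 1], "C") - at(res_ids[i - 1], "O")
            h = at(ri, "N") + 1.01 * v / np.linalg.norm(v)
        else:
            continue
        for j, rj in enumerate(res_ids):
            if abs(i - j) < 2:
                continue
            n, c, o = at(ri, "N"), at(rj, "C"), at(rj, "O")
            e = params.q1q2_factor * params.f_dimensional * (
                1 / np.linalg.norm(n - o) + 1 / np.linalg.norm(h - c)
                - 1 / np.linalg.norm(h - o) - 1 / np.linalg.norm(n - c)
            )
            if e < params.e_cutoff:
                bonds.append((ri, rj, e))
    return sorted(bonds)


def oracle_assign(frame, topology, params=SSParams()):
    """Pattern rules applied literally to the oracle bond list."""
    res_ids = [r for _, r, _ in topology.residues()]
    nres = len(res_ids)
    pos = {r: k for k, r in enumerate(res_ids)}
    hb = np.zeros((nres, nres), dtype=bool)
    for d, a, _ in oracle_hbonds(frame, topology, params):
        hb[pos[d], pos[a]] = True

    def bond(d, a):
        return 0 <= d < nres and 0 <= a < nres and hb[d, a]

    def t(n, i):
        return bond(i + n, i)

    helix = [False] * nres
    g_helix = [False] * nres
    for i in range(1, nres):
        if t(4, i - 1) and t(4, i):
            for k in range(i, min(i + 4, nres)):
                helix[k] = True
        if t(3, i - 1) and t(3, i):
            for k in range(i, min(i + 3, nres)):
                g_helix[k] = True

    bridges = set()
    for i in range(nres):
        for j in range(nres):
            if abs(i - j) < 3:
                continue
            para = (bond(j, i - 1) and bond(i + 1, j)) or (bond(i, j - 1) and bond(j + 1, i))
            anti = (bond(j, i) and bond(i, j)) or (bond(j + 1, i - 1) and bond(i + 1, j - 1))
            if para or anti:
                bridges.add((i, j))
    strand = [False] * nres
    bridge = [False] * nres
    for i, j in bridges:
        if any((i + di, j + dj) in bridges for di in (-1, 1) for dj in (-1, 1)):
            strand[i] = strand[j] = True
        else:
            bridge[i] = bridge[j] = True

    turn = [False] * nres
    for n in (3, 4, 5):
        for i in range(nres):
            if t(n, i):
                for k in range(i + 1, min(i + n, nres)):
                    turn[k] = True

    codes = []
    for i in range(nres):
        if helix[i]:
            codes.append("H")
        elif g_helix[i]:
            codes.append("G")
        elif strand[i]:
            codes.append("E")
        elif bridge[i]:
            codes.append("B")
        elif turn[i]:
            codes.append("T")
        else:
            codes.append("C")
    return np.array(codes)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

class TestBackboneHbonds:
    def test_ideal_helix_has_i_to_i4_ladder(self, ideal_helix_12):
        hb = backbone_hbonds(ideal_helix_12.frames[0], ideal_helix_12.topology)
        pairs = {(d, a) for d, a, _ in hb}
        assert pairs == {(i + 4, i) for i in range(1, 9)}
        assert all(e < -0.5 for _, _, e in hb)

    def test_two_residue_peptide_is_empty(self):
        t = gen_peptide_trajectory(PeptideGenSpec(seed=2, n_res=2, n_frames=1))
        assert backbone_hbonds(t.frames[0], t.topology) == []

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_bruteforce_enumeration(self, seed):
        spec = PeptideGenSpec(
            seed=seed, n_res=15, n_frames=2,
            segments=(Segment(2, 9, "alpha", 0.7),),
        )
        traj = gen_peptide_trajectory(spec)
        for f in range(traj.n_frames):
            got = backbone_hbonds(traj.frames[f], traj.topology)
            expect = oracle_hbonds(traj.frames[f], traj.topology)
            assert [(d, a) for d, a, _ in got] == [(d, a) for d, a, _ in expect]
            np.testing.assert_allclose(
                [e for _, _, e in got], [e for _, _, e in expect], atol=1e-9
            )

    def test_missing_backbone_atom_names_residue(self):
        t = gen_peptide_trajectory(PeptideGenSpec(seed=2, n_res=4, n_frames=1))
        broken = Structure([a for a in t.topology.atoms if not (a.res_seq == 3 and a.name == "O")])
        frame = t.frames[0][[i for i, a in enumerate(t.topology.atoms) if not (a.res_seq == 3 and a.name == "O")]]
        with pytest.raises(AssignmentError, match="3"):
            backbone_hbonds(frame, broken)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

class TestAssignSS:
    def test_ideal_helix_interior_is_h(self, ideal_helix_12):
        codes = assign_ss(ideal_helix_12.frames[0], ideal_helix_12.topology)
        assert "".join(codes[1:11]) == "H" * 10
        # chain termini can never satisfy the two-consecutive-turn rule
        assert codes[0] != "H" and codes[-1] != "H"

    def test_extended_chain_has_no_helix(self):
        spec = PeptideGenSpec(
            seed=1, n_res=12, segments=(), n_frames=1,
            coil_dihedral_jitter=0.0, coil_phi=180.0, coil_psi=180.0,
        )
        t = gen_peptide_trajectory(spec)
        codes = assign_ss(t.frames[0], t.topology)
        assert set(codes) <= {"C", "T"}

    def test_planted_helix_confined_to_segment(self):
        spec = PeptideGenSpec(
            seed=7, n_res=43, segments=(Segment(3, 12, "alpha", 1.0),), n_frames=5
        )
        traj = gen_peptide_trajectory(spec)
        for f in range(traj.n_frames):
            codes = assign_ss(traj.frames[f], traj.topology)
            h_res = {traj.topology.residues()[i][1] for i in np.nonzero(codes == "H")[0]}
            assert h_res, "planted helix not detected"
            assert h_res <= set(range(2, 14))  # 3-12 with one residue of slack

    @pytest.mark.parametrize("seed", range(20, 26))
    def test_matches_literal_pattern_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = PeptideGenSpec(
            seed=seed, n_res=int(rng.integers(5, 16)), n_frames=3,
            segments=(), coil_dihedral_jitter=60.0,
            coil_phi=float(rng.uniform(-150, -60)), coil_psi=float(rng.uniform(-60, 160)),
        )
        traj = gen_peptide_trajectory(spec)
        for f in range(traj.n_frames):
            got = assign_ss(traj.frames[f], traj.topology)
            np.testing.assert_array_equal(got, oracle_assign(traj.frames[f], traj.topology))

    def test_alphabet_closed(self, planted_tail_2000):
        m = ss_matrix(
            Trajectory(planted_tail_2000.topology, planted_tail_2000.frames[:50], 25.0)
        )
        assert set(np.unique(m.labels)) <= set(SS_CODES)


class TestSSMatrix:
    def test_single_frame_equals_assign(self, ideal_helix_12):
        m = ss_matrix(ideal_helix_12)
        np.testing.assert_array_equal(
            m.labels[0], assign_ss(ideal_helix_12.frames[0], ideal_helix_12.topology)
        )
        assert m.labels.shape == (1, 12)

    def test_constant_trajectory_rows_identical(self, ideal_helix_12):
        frames = np.repeat(ideal_helix_12.frames, 20, axis=0)
        m = ss_matrix(Trajectory(ideal_helix_12.topology, frames, 25.0))
        assert (m.labels == m.labels[0]).all()
        np.testing.assert_allclose(m.times, np.arange(20) * 25.0)

    def test_melt_trajectory_h_rows_at_planted_frames(self):
        on = gen_peptide_trajectory(PeptideGenSpec(
            seed=30, n_res=20, segments=(Segment(4, 15, "alpha", 1.0),), n_frames=10))
        off = gen_peptide_trajectory(PeptideGenSpec(
            seed=31, n_res=20, segments=(), n_frames=10))
        frames = np.concatenate([on.frames, off.frames])
        m = ss_matrix(Trajectory(on.topology, frames, 25.0))
        has_h = (m.labels == "H").any(axis=1)
        assert has_h[:10].all()
        assert not has_h[10:].any()


class TestOccupancy:
    def test_constant_matrix_gives_unit_occupancy(self, ideal_helix_12):
        frames = np.repeat(ideal_helix_12.frames, 10, axis=0)
        occ = occupancy(ss_matrix(Trajectory(ideal_helix_12.topology, frames, 25.0)))
        assert occ.loc[5, "H"] == 1.0

    def test_rows_sum_to_one(self, planted_tail_2000):
        m = ss_matrix(Trajectory(planted_tail_2000.topology, planted_tail_2000.frames[:100], 25.0))
        occ = occupancy(m)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)

    def test_60_40_persistence_recovered(self):
        traj = gen_peptide_trajectory(PeptideGenSpec(
            seed=42, n_res=43, segments=(Segment(3, 12, "alpha", 0.6),), n_frames=2000))
        occ = occupancy(ss_matrix(traj))
        interior = occ.loc[5:10, "H"]
        assert (np.abs(interior - 0.6) <= 0.03).all()
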