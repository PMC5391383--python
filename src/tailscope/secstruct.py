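"""Backbone hydrogen bonds and DSSP-style secondary-structure assignment.

Assignment follows the Kabsch–Sander electrostatic model: an amide-carbonyl
pair is hydrogen bonded when

    E = q1*q2 * f * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) < -0.5 kcal/mol

with q1*q2 = 0.084 e² and f = 332 kcal·Å/(mol·e²).  From the bond pattern a
reduced six-class alphabet is assigned:

    H  α-helix          (runs of ≥2 consecutive i→i+4 turns)
    G  3₁₀-helix        (runs of ≥2 consecutive i→i+3 turns)
    E  β-strand         (bridges extended into ladders)
    B  isolated β-bridge
    T  hydrogen-bonded turn
    C  coil / other

π-helix patterns are not assigned a class of their own (their turns can still
contribute T).  Amide hydrogens are rebuilt geometrically when the input has
none, so minimized heavy-atom ensembles are handled directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AssignmentError
from .structio import Structure, Trajectory

__all__ = [
    "SSParams",
    "SS_CODES",
    "SSMatrix",
    "backbone_hbonds",
    "assign_ss",
    "ss_matrix",
    "occupancy",
]

SS_CODES = ("H", "G", "E", "B", "T", "C")


@dataclass(frozen=True)
class SSParams:
    """Hydrogen-bond energy model and pattern-rule parameters."""

    q1q2_factor: float = 0.084  # partial-charge product, e²
    f_dimensional: float = 332.0  # kcal·Å/(mol·e²)
    e_cutoff: float = -0.5  # kcal/mol; a pair is bonded below this
    min_helix_run: int = 2  # consecutive n-turns required for a helix

    def __post_init__(self):
        if not self.e_cutoff < 0:
            raise ValueError("e_cutoff must be negative")


@dataclass
class SSMatrix:
    """Frame × residue grid of secondary-structure codes."""

    labels: np.ndarray  # (n_frames, n_res), dtype '<U1'
    residue_ids: list[int]
    times: np.ndarray  # ps

    def __post_init__(self):
        if self.labels.shape != (len(self.times), len(self.residue_ids)):
            raise ValueError("label grid does not match residue_ids/times")
        bad = set(np.unique(self.labels)) - set(SS_CODES)
        if bad:
            raise ValueError(f"invalid secondary-structure codes {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.labels, index=pd.Index(self.times, name="time_ps"),
            columns=pd.Index(self.residue_ids, name="res_seq"),
        )


class _Backbone:
    """Per-residue backbone atom indices for one chain, in residue order."""

    def __init__(self, topology: Structure):
        res = topology.residues()
        chains = {c for c, _, _ in res}
        if len(chains) != 1:
            raise AssignmentError(
                f"secondary structure expects a single-chain peptide, got chains {sorted(chains)}"
            )
        self.res_ids = [r for _, r, _ in res]
        self.res_names = [n for _, _, n in res]
        idx = {(a.res_seq, a.name): i for i, a in enumerate(topology.atoms)}
        self.n_idx, self.ca_idx, self.c_idx, self.o_idx = [], [], [], []
        self.h_idx: list[int | None] = []
        for r in self.res_ids:
            for name, store in (("N", self.n_idx), ("CA", self.ca_idx), ("C", self.c_idx), ("O", self.o_idx)):
                if (r, name) not in idx:
                    raise AssignmentError(f"residue {r} lacks backbone atom {name}")
                store.append(idx[(r, name)])
            self.h_idx.append(idx.get((r, "H")))


def _hbond_energies(frames: np.ndarray, bb: _Backbone, params: SSParams) -> np.ndarray:
    """Kabsch–Sander energies, shape (n_frames, n_res, n_res).

    Entry [f, i, j] is the energy of the bond donated by the amide of residue
    i to the carbonyl of residue j; non-bondable pairs hold +inf.
    """
    n = frames[:, bb.n_idx]      # (F, R, 3)
    c = frames[:, bb.c_idx]
    o = frames[:, bb.o_idx]
    nres = len(bb.res_ids)

    # Amide H: use the file's H where present, rebuild anti to the preceding
    # carbonyl otherwise (the standard reconstruction for heavy-atom input).
    h = np.full_like(n, np.nan)
    has_donor = np.zeros(nres, dtype=bool)
    for i in range(nres):
        if bb.res_names[i] == "PRO":
            continue  # no amide hydrogen
        if bb.h_idx[i] is not None:
            h[:, i] = frames[:, bb.h_idx[i]]
            has_donor[i] = True
        elif i > 0:
            v = c[:, i - 1] - o[:, i - 1]
            v /= np.linalg.norm(v, axis=-1, keepdims=True)
            h[:, i] = n[:, i] + 1.01 * v
            has_donor[i] = True
        # residue 1 without an explicit H has no reconstructible donor

    def dist(a, b):
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        e = (
            params.q1q2_factor
            * params.f_dimensional
            * (1.0 / dist(n, o) + 1.0 / dist(h, c) - 1.0 / dist(h, o) - 1.0 / dist(n, c))
        )
    e = np.where(np.isfinite(e), e, np.inf)
    ii, jj = np.meshgrid(np.arange(nres), np.arange(nres), indexing="ij")
    e[:, np.abs(ii - jj) < 2] = np.inf
    e[:, ~has_donor, :] = np.inf
    return e


def backbone_hbonds(
    frame: np.ndarray, topology: Structure, params: SSParams = SSParams()
) -> list[tuple[int, int, float]]:
    """All bonded (donor_res_seq, acceptor_res_seq, energy) triples for one frame."""
    bb = _Backbone(topology)
    e = _hbond_energies(np.asarray(frame, dtype=float)[None], bb, params)[0]
    out = []
    for i, j in zip(*np.nonzero(e < params.e_cutoff)):
        out.append((bb.res_ids[i], bb.res_ids[j], float(e[i, j])))
    return sorted(out)


def _shift(mat: np.ndarray, di: int, dj: int) -> np.ndarray:
    """out[i, j] = mat[i+di, j+dj] where in range, False elsewhere."""
    n, m = mat.shape
    out = np.zeros_like(mat)
    r0, r1 = max(0, -di), min(n, n - di)
    c0, c1 = max(0, -dj), min(m, m - dj)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = mat[r0 + di : r1 + di, c0 + dj : c1 + dj]
    return out


def _codes_from_bonds(hb: np.ndarray, min_run: int) -> np.ndarray:
    """Apply the pattern rules to a boolean donor×acceptor bond matrix.

    ``hb[d, a]`` is True when the amide of residue d donates to the carbonyl
    of residue a (0-based positions along the chain).
    """
    nres = hb.shape[0]

    def turn(n: int) -> np.ndarray:
        """t[i] true when the carbonyl of i bonds the amide of i+n."""
        t = np.zeros(nres, dtype=bool)
        if nres > n:
            t[: nres - n] = hb[np.arange(n, nres), np.arange(nres - n)]
        return t

    t3, t4, t5 = turn(3), turn(4), turn(5)

    def helix_mask(t: np.ndarray, length: int) -> np.ndarray:
        mask = np.zeros(nres, dtype=bool)
        for i in range(min_run - 1, nres):
            if t[i - min_run + 1 : i + 1].all():
                mask[i : i + length] = True
        return mask

    helix = helix_mask(t4, 4)
    g_helix = helix_mask(t3, 3)

    # β-bridge pair matrix (symmetric by construction); bmat[i, j] true when
    # residues i and j form a parallel or antiparallel bridge.
    hbt = hb.T
    para = (_shift(hbt, -1, 0) & _shift(hb, 1, 0)) | (
        _shift(hb, 0, -1) & _shift(hbt, 0, 1)
    )
    anti = (hbt & hb) | (_shift(hbt, -1, 1) & _shift(hb, 1, -1))
    bmat = para | anti
    ii, jj = np.meshgrid(np.arange(nres), np.arange(nres), indexing="ij")
    bmat &= np.abs(ii - jj) >= 3

    neighbor = (
        _shift(bmat, 1, 1) | _shift(bmat, 1, -1) | _shift(bmat, -1, 1) | _shift(bmat, -1, -1)
    )
    strand_pairs = bmat & neighbor
    iso_pairs = bmat & ~neighbor
    strand = strand_pairs.any(axis=1) | strand_pairs.any(axis=0)
    bridge = iso_pairs.any(axis=1) | iso_pairs.any(axis=0)

    turn_mark = np.zeros(nres, dtype=bool)
    for n, t in ((3, t3), (4, t4), (5, t5)):
        for i in np.nonzero(t)[0]:
            turn_mark[i + 1 : i + n] = True

    codes = np.full(nres, "C", dtype="<U1")
    codes[turn_mark] = "T"
    codes[bridge & (codes != "H")] = "B"
    codes[strand] = "E"
    codes[g_helix & ~helix] = "G"
    codes[helix] = "H"
    return codes


def assign_ss(
    frame: np.ndarray, topology: Structure, params: SSParams = SSParams()
) -> np.ndarray:
    """Per-residue secondary-structure codes for one frame."""
    bb = _Backbone(topology)
    e = _hbond_energies(np.asarray(frame, dtype=float)[None], bb, params)[0]
    return _codes_from_bonds(e < params.e_cutoff, params.min_helix_run)


def ss_matrix(traj: Trajectory, params: SSParams = SSParams()) -> SSMatrix:
    """Secondary-structure evolution over a whole trajectory."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    bb = _Backbone(traj.topology)
    energies = _hbond_energies(traj.frames, bb, params)
    bonded = energies < params.e_cutoff
    labels = np.stack(
        [_codes_from_bonds(bonded[f], params.min_helix_run) for f in range(traj.n_frames)]
    )
    return SSMatrix(labels=labels, residue_ids=list(bb.res_ids), times=traj.times)


def occupancy(m: SSMatrix) -> pd.DataFrame:
    """Fraction of frames each residue spends in each class (rows sum to 1)."""
    n_frames = m.labels.shape[0]
    if n_frames == 0:
        raise ValueError("empty matrix")
    data = {
        code: (m.labels == code).sum(axis=0) / n_frames for code in SS_CODES
    }
    df = pd.DataFrame(data, index=pd.Index(m.residue_ids, name="res_seq"))
    assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)
    return df
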