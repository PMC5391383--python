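"""Pairwise Cα RMSD, single-linkage clustering and representative extraction.

Clustering follows the threshold-graph convention: frames i and j are linked
when their superposed Cα RMSD is at or below the cutoff, and clusters are the
connected components of that graph (exactly what single-linkage at a fixed
cutoff produces).  The "median" structure of a cluster is its medoid — the
member with minimal summed RMSD to all other members; divergent conformers
are never coordinate-averaged.

RMSD is always computed after optimal rigid superposition: translation and
rotation of a free peptide carry no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._geometry import kabsch
from .errors import SelectionError
from .structio import Structure, Trajectory

__all__ = [
    "RMSDMatrix",
    "Clustering",
    "kabsch_rmsd",
    "rmsd_matrix",
    "single_linkage",
    "representative",
]


@dataclass
class RMSDMatrix:
    """All-vs-all superposed RMSD in Å for a frame set."""

    values: np.ndarray  # (n, n)
    atom_selection: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(np.diag(v), 0.0, atol=1e-6):
            raise ValueError("RMSD matrix diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("RMSD matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("RMSD values must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    """Frame-to-cluster assignment; cluster ids are population ranks (0 = largest)."""

    assignment: np.ndarray  # (n,) cluster id per frame
    cutoff: float
    medoids: list[int]  # per cluster id, the medoid frame index

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.assignment == cluster_id)[0]

    def populations(self) -> list[int]:
        return [int((self.assignment == k).sum()) for k in range(self.n_clusters)]

    def to_frame(self) -> pd.DataFrame:
        is_medoid = np.zeros(len(self.assignment), dtype=bool)
        is_medoid[self.medoids] = True
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.assignment)),
                "cluster": self.assignment,
                "is_medoid": is_medoid,
            }
        )


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD between matched point sets after optimal rigid superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected matched (n, 3) coordinate sets")
    if a.shape[0] < 3:
        warnings.warn("fewer than 3 points: superposition is under-determined")
    else:
        # collinearity leaves a free rotation about the common axis
        for pts in (a, b):
            s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
            if s[1] < 1e-8 * max(s[0], 1.0):
                warnings.warn("collinear point set: superposition is ill-conditioned")
                break
    return kabsch(a, b)[2]


def rmsd_matrix(
    traj: Trajectory, selection: tuple[int, int] | None = None
) -> RMSDMatrix:
    """All-vs-all Cα RMSD over frames, optionally restricted to a residue range.

    ``selection=(1, 15)`` reproduces the tip re-clustering geometry (first 15
    N-terminal α-carbons).
    """
    idx = traj.topology.ca_indices(selection)
    sub = traj.frames[:, idx, :]
    n = traj.n_frames
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch(sub[i], sub[j])[2]
    desc = f"Cα {selection[0]}-{selection[1]}" if selection else "Cα all"
    return RMSDMatrix(m, atom_selection=desc)


def single_linkage(m: RMSDMatrix, cutoff: float) -> Clustering:
    """Connected components of the graph with edges where RMSD <= cutoff.

    Clusters are ordered by descending population, ties broken by the lowest
    member frame index; the medoid minimizes summed RMSD within its cluster
    (ties again to the lowest frame index).
    """
    adj = csr_matrix(m.values <= cutoff)
    _, raw_labels = connected_components(adj, directed=False)
    comp_ids = np.unique(raw_labels)
    order = sorted(
        comp_ids,
        key=lambda c: (-int((raw_labels == c).sum()), int(np.nonzero(raw_labels == c)[0][0])),
    )
    relabel = {c: k for k, c in enumerate(order)}
    assignment = np.array([relabel[c] for c in raw_labels])
    medoids = []
    for k in range(len(order)):
        members = np.nonzero(assignment == k)[0]
        sums = m.values[np.ix_(members, members)].sum(axis=1)
        medoids.append(int(members[int(np.argmin(sums))]))
    return Clustering(assignment=assignment, cutoff=float(cutoff), medoids=medoids)


def representative(traj: Trajectory, c: Clustering, k: int = 1) -> Structure:
    """Medoid frame of the k-th most populated cluster (k is 1-based rank)."""
    if not 1 <= k <= c.n_clusters:
        raise SelectionError(f"cluster rank {k} out of range (1..{c.n_clusters})")
    frame = c.medoids[k - 1]
    label = (
        f"{traj.topology.label} cluster {k} medoid, frame {frame}"
        f" @ {frame * traj.dt:g} ps"
    )
    return traj.frame_structure(frame, label=label)
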