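"""Docking-grid bookkeeping, best-pose ranking and contact classification.

The docking search itself is out of scope; this module consumes pose tables
(per-pose binding energies keyed by grid cell, from any engine) and pose /
receptor coordinates.  Binding energies use the convention where larger is
more favorable (energy *obtained from* binding); use ``negate_energies`` on
input for engines that report released energy as negative values.

A reference pose-energy table for the four H3 tail-tip isoform structures
(three unmodified tip clusters plus hyperacetylated, active and inactive
tips, nine 3×3 grid cells each) ships with the package and is the default
input of the ranking stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SelectionError
from .structio import Structure

__all__ = [
    "GridSpec",
    "PoseTable",
    "ContactReport",
    "make_grid",
    "expected_pose_total",
    "best_pose",
    "load_reference_pose_table",
    "find_contacts",
    "contact_summary",
]

#: residue names treated as nucleic acid when tagging receptor atoms
DNA_RES_NAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}


@dataclass(frozen=True)
class GridSpec:
    """Overlapping axis-aligned grid cells over a receptor's xy bounding box.

    Cells are labelled row-major A1..A{cols}, B1..; each interior edge is
    expanded by ``overlap_frac`` of the base cell width so neighboring cells
    overlap.  Cells span the full z extent of the box.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmin: float
    zmax: float
    rows: int
    cols: int
    overlap_frac: float = 0.25

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if not 0.0 <= self.overlap_frac <= 0.5:
            raise ValueError("overlap_frac must be in [0, 0.5]")

    @property
    def labels(self) -> list[str]:
        return [
            f"{ascii_uppercase[r]}{c + 1}" for r in range(self.rows) for c in range(self.cols)
        ]

    def cell_bounds(self, label: str) -> tuple[float, float, float, float]:
        """(xlo, xhi, ylo, yhi) of a cell after overlap expansion.

        Rows run along y, columns along x.
        """
        if label not in self.labels:
            raise SelectionError(f"unknown grid cell '{label}'")
        r = ascii_uppercase.index(label[0])
        c = int(label[1:]) - 1
        w = (self.xmax - self.xmin) / self.cols
        h = (self.ymax - self.ymin) / self.rows
        xlo = self.xmin + c * w - (self.overlap_frac * w if c > 0 else 0.0)
        xhi = self.xmin + (c + 1) * w + (self.overlap_frac * w if c < self.cols - 1 else 0.0)
        ylo = self.ymin + r * h - (self.overlap_frac * h if r > 0 else 0.0)
        yhi = self.ymin + (r + 1) * h + (self.overlap_frac * h if r < self.rows - 1 else 0.0)
        return xlo, xhi, ylo, yhi

    def cells_containing(self, point: np.ndarray) -> list[str]:
        x, y = float(point[0]), float(point[1])
        out = []
        for label in self.labels:
            xlo, xhi, ylo, yhi = self.cell_bounds(label)
            if xlo <= x <= xhi and ylo <= y <= yhi:
                out.append(label)
        return out


def make_grid(
    receptor: Structure, rows: int = 3, cols: int = 3, overlap_frac: float = 0.25
) -> GridSpec:
    if len(receptor) == 0:
        raise ValueError("empty receptor")
    xyz = receptor.coords
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    return GridSpec(
        xmin=float(lo[0]), xmax=float(hi[0]),
        ymin=float(lo[1]), ymax=float(hi[1]),
        zmin=float(lo[2]), zmax=float(hi[2]),
        rows=rows, cols=cols, overlap_frac=overlap_frac,
    )


def expected_pose_total(g: GridSpec, per_cell: int) -> int:
    """Total poses produced by a run yielding ``per_cell`` poses per grid cell."""
    if per_cell < 1:
        raise ValueError("per_cell must be >= 1")
    return g.rows * g.cols * per_cell


@dataclass
class PoseTable:
    """Per-pose binding energies keyed by (structure_label, cell_label)."""

    df: pd.DataFrame  # columns: structure_label, cell_label, binding_energy[, pose_file]

    REQUIRED = ("structure_label", "cell_label", "binding_energy")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"pose table missing columns {missing}")
        if not np.isfinite(self.df["binding_energy"].to_numpy(dtype=float)).all():
            raise ValueError("pose table contains non-finite energies")

    @classmethod
    def read_csv(cls, path: str | Path, negate_energies: bool = False) -> "PoseTable":
        df = pd.read_csv(path)
        if negate_energies:
            df = df.assign(binding_energy=-df["binding_energy"])
        return cls(df)

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.df["structure_label"]))


def load_reference_pose_table() -> PoseTable:
    """The packaged tip-isoform pose-energy table (3×3 grid, 6 tip structures)."""
    with resources.files("tailscope.data").joinpath("tip_pose_energies.csv").open() as fh:
        return PoseTable(pd.read_csv(fh))


def _cell_sort_key(cell: str) -> tuple[int, int]:
    return (ascii_uppercase.index(cell[0]), int(cell[1:]))


def best_pose(t: PoseTable, structure_label: str) -> tuple[str, float]:
    """Grid cell and energy of the most favorable pose for one structure.

    Larger energy wins; exact ties go to the first cell in A1..C3 label order.
    """
    rows = t.df[t.df["structure_label"] == structure_label]
    if rows.empty:
        raise SelectionError(f"no poses for structure '{structure_label}'")
    ordered = sorted(
        rows.itertuples(index=False),
        key=lambda r: (-r.binding_energy, _cell_sort_key(r.cell_label)),
    )
    top = ordered[0]
    return top.cell_label, float(top.binding_energy)


@dataclass
class ContactReport:
    """Atom-pair contacts between a docked tip and a receptor.

    ``df`` has one row per pair within the cutoff with boolean ``is_hbond`` /
    ``is_hydrophobic`` class flags (both subsets of the total contact set)
    and the receptor component the atom belongs to (``DNA`` or
    ``chain_<id>``).
    """

    df: pd.DataFrame
    cutoff: float


def _apolar_carbons(s: Structure) -> np.ndarray:
    """Boolean mask: carbon atoms with no covalently bonded N/O (within 1.7 Å)."""
    xyz = s.coords
    elems = np.array([a.element.upper() for a in s.atoms])
    mask = elems == "C"
    if not mask.any():
        return mask
    polar_idx = np.nonzero((elems == "N") | (elems == "O"))[0]
    if polar_idx.size == 0:
        return mask
    tree = cKDTree(xyz[polar_idx])
    near = tree.query_ball_point(xyz[mask], r=1.7)
    out = mask.copy()
    out[np.nonzero(mask)[0]] = [len(nb) == 0 for nb in near]
    return out


def _attached_h(s: Structure, heavy_idx: int) -> list[int]:
    xyz = s.coords
    out = []
    for i, a in enumerate(s.atoms):
        if a.element.upper() == "H" and np.linalg.norm(xyz[i] - xyz[heavy_idx]) <= 1.25:
            out.append(i)
    return out


def _is_hbond(tip: Structure, rec: Structure, it: int, ir: int, dist: float) -> bool:
    """Donor-acceptor N/O pair within 3.5 Å; X-H...Y angle >= 135° when an H
    is resolved on either partner, distance-only otherwise."""
    et = tip.atoms[it].element.upper()
    er = rec.atoms[ir].element.upper()
    if et not in ("N", "O") or er not in ("N", "O") or dist > 3.5:
        return False
    pt, pr = tip.coords[it], rec.coords[ir]
    candidates = []  # (H position, donor position, acceptor position)
    for h in _attached_h(tip, it):
        candidates.append((tip.coords[h], pt, pr))
    for h in _attached_h(rec, ir):
        candidates.append((rec.coords[h], pr, pt))
    if not candidates:
        return True  # heavy-atom-only input: fall back to the distance rule
    for hpos, dpos, apos in candidates:
        u = dpos - hpos
        v = apos - hpos
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= 135.0:
            return True
    return False


def find_contacts(tip: Structure, receptor: Structure, cutoff: float = 5.0) -> ContactReport:
    """All inter-structure atom pairs within ``cutoff`` Å, classified.

    Hydrogen bonds and hydrophobic (apolar C–C) contacts are flagged subsets
    of the total pair set; every receptor atom is tagged DNA or protein chain.
    """
    if len(tip) == 0 or len(receptor) == 0:
        raise ValueError("tip and receptor must be nonempty")
    pairs = cKDTree(tip.coords).query_ball_tree(cKDTree(receptor.coords), r=cutoff)
    rec_apolar = _apolar_carbons(receptor)
    tip_apolar = _apolar_carbons(tip)
    rows = []
    for it, nbrs in enumerate(pairs):
        for ir in nbrs:
            d = float(np.linalg.norm(tip.coords[it] - receptor.coords[ir]))
            ra = receptor.atoms[ir]
            component = "DNA" if ra.res_name in DNA_RES_NAMES else f"chain_{ra.chain_id}"
            rows.append(
                {
                    "tip_atom": f"{tip.atoms[it].res_name}{tip.atoms[it].res_seq}:{tip.atoms[it].name}",
                    "receptor_atom": f"{ra.chain_id}/{ra.res_name}{ra.res_seq}:{ra.name}",
                    "distance_A": d,
                    "receptor_component": component,
                    "is_hbond": _is_hbond(tip, receptor, it, ir, d),
                    "is_hydrophobic": bool(tip_apolar[it] and rec_apolar[ir]),
                }
            )
    cols = [
        "tip_atom", "receptor_atom", "distance_A",
        "receptor_component", "is_hbond", "is_hydrophobic",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return ContactReport(df=df, cutoff=float(cutoff))


def contact_summary(r: ContactReport) -> pd.DataFrame:
    """Contact counts per class and per receptor component."""
    if r.df.empty:
        return pd.DataFrame(columns=["receptor_component", "total", "hbond", "hydrophobic"])
    g = r.df.groupby("receptor_component", sort=True)
    out = pd.DataFrame(
        {
            "total": g.size(),
            "hbond": g["is_hbond"].sum().astype(int),
            "hydrophobic": g["is_hydrophobic"].sum().astype(int),
        }
    ).reset_index()
    return out
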