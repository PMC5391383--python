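"""Tetranucleosome reach model: quartile shells and site reachability.

Each histone H3 anchor (the P43 Cα where the tail joins the core) carries a
spherical annulus whose inner and outer radii are the first and third
quartiles of that tail's reach distribution — the band where most per-frame
tail lengths fall.  An annotated site (a transplanted best binding position,
the H2A/H2B acidic patch, linker DNA) counts as reachable when its nearest
point to the anchor lies inside the band; reachable sites are then labelled
intranucleosomal, internucleosomal within the same stack, or on the adjacent
stack, which is the geometric core of the chromatin accessibility argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import kabsch
from .errors import SelectionError
from .reach import ReachSummary
from .structio import Structure

__all__ = [
    "Nucleosome",
    "Site",
    "NucleosomeAssembly",
    "ReachShell",
    "build_shells",
    "site_reachable",
    "classify_reachable_sites",
    "transplant_site",
]

SITE_KINDS = ("tip_binding_site", "acidic_patch", "linker_DNA")
RELATIONS = (
    "intranucleosomal",
    "internucleosomal_same_stack",
    "internucleosomal_adjacent_stack",
)


@dataclass
class Nucleosome:
    id: str
    stack_id: str
    structure: Structure | None
    anchors: list[np.ndarray]  # H3 P43 Cα positions (two per nucleosome)

    def __post_init__(self):
        self.anchors = [np.asarray(a, dtype=float).reshape(3) for a in self.anchors]


@dataclass
class Site:
    site_id: str
    nucleosome_id: str
    coords: np.ndarray  # (k, 3)
    kind: str

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3 or self.coords.shape[0] == 0:
            raise ValueError(f"site {self.site_id}: coords must be a nonempty (k, 3) array")
        if self.kind not in SITE_KINDS:
            raise ValueError(f"site {self.site_id}: unknown kind '{self.kind}'")


@dataclass
class NucleosomeAssembly:
    nucleosomes: list[Nucleosome]
    sites: list[Site] = field(default_factory=list)

    def __post_init__(self):
        if not self.nucleosomes:
            raise ValueError("assembly needs at least one nucleosome")
        ids = {n.id for n in self.nucleosomes}
        if len(ids) != len(self.nucleosomes):
            raise ValueError("duplicate nucleosome ids")
        for s in self.sites:
            if s.nucleosome_id not in ids:
                raise ValueError(f"site {s.site_id} references unknown nucleosome {s.nucleosome_id}")

    def nucleosome(self, nid: str) -> Nucleosome:
        for n in self.nucleosomes:
            if n.id == nid:
                return n
        raise SelectionError(f"no nucleosome '{nid}'")

    def anchor_labels(self) -> list[tuple[str, int]]:
        return [(n.id, k) for n in self.nucleosomes for k in range(len(n.anchors))]


@dataclass(frozen=True)
class ReachShell:
    """Anchor-centred spherical annulus between the Q1 and Q3 reach radii."""

    center: tuple[float, float, float]
    r_inner: float
    r_outer: float
    anchor_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.r_inner <= self.r_outer:
            raise ValueError("need 0 <= r_inner <= r_outer")


def build_shells(assembly: NucleosomeAssembly, summary: ReachSummary) -> list[ReachShell]:
    """One shell per H3 anchor, radii from the reach quartiles."""
    shells = []
    for n in assembly.nucleosomes:
        if not n.anchors:
            raise ValueError(f"nucleosome {n.id} has no anchors")
        for k, a in enumerate(n.anchors):
            shells.append(
                ReachShell(
                    center=tuple(float(x) for x in a),
                    r_inner=float(summary.q1),
                    r_outer=float(summary.q3),
                    anchor_id=f"{n.id}:{k}",
                )
            )
    return shells


def site_reachable(
    shell: ReachShell, site_coords: np.ndarray, mode: str = "nearest"
) -> bool:
    """Whether a (possibly multi-point) site falls inside the shell's band.

    ``mode='nearest'``: the nearest site point decides (a tail tip need only
    touch part of a binding surface).  ``mode='all'``: every point must lie
    in the band.
    """
    pts = np.atleast_2d(np.asarray(site_coords, dtype=float))
    if pts.size == 0:
        raise ValueError("empty site")
    d = np.linalg.norm(pts - np.asarray(shell.center), axis=1)
    in_band = (d >= shell.r_inner) & (d <= shell.r_outer)
    if mode == "nearest":
        dmin = d.min()
        return bool(shell.r_inner <= dmin <= shell.r_outer)
    if mode == "all":
        return bool(in_band.all())
    raise ValueError(f"unknown mode '{mode}'")


def classify_reachable_sites(
    assembly: NucleosomeAssembly,
    shells: list[ReachShell],
    mode: str = "nearest",
) -> pd.DataFrame:
    """Per anchor × site table: distance, reachability and stack relation."""
    nuc_by_id = {n.id: n for n in assembly.nucleosomes}
    rows = []
    for shell in shells:
        anchor_nuc_id = shell.anchor_id.split(":")[0]
        anchor_nuc = nuc_by_id[anchor_nuc_id]
        for site in assembly.sites:
            site_nuc = nuc_by_id[site.nucleosome_id]
            if site.nucleosome_id == anchor_nuc_id:
                relation = "intranucleosomal"
            elif site_nuc.stack_id == anchor_nuc.stack_id:
                relation = "internucleosomal_same_stack"
            else:
                relation = "internucleosomal_adjacent_stack"
            d = float(
                np.linalg.norm(site.coords - np.asarray(shell.center), axis=1).min()
            )
            rows.append(
                {
                    "anchor": shell.anchor_id,
                    "site": site.site_id,
                    "site_kind": site.kind,
                    "distance_A": d,
                    "relation": relation,
                    "reachable": site_reachable(shell, site.coords, mode=mode),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["anchor", "site", "site_kind", "distance_A", "relation", "reachable"],
    )


def transplant_site(
    pose_coords: np.ndarray, source_ncp: Structure, target_ncp: Structure
) -> np.ndarray:
    """Map site/pose coordinates from one nucleosome onto another.

    The rigid transform is the Kabsch superposition of the octamer-core atoms
    the two nucleosomes share (matched by chain_id/res_seq/atom name), applied
    to the pose coordinates.
    """
    src_keys = {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(source_ncp.atoms)}
    tgt_keys = {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(target_ncp.atoms)}
    common = [k for k in src_keys if k in tgt_keys]
    if len(common) < 3:
        raise SelectionError(
            f"source and target share only {len(common)} atoms; need >= 3 for superposition"
        )
    src = source_ncp.coords[[src_keys[k] for k in common]]
    tgt = target_ncp.coords[[tgt_keys[k] for k in common]]
    rot, t, _ = kabsch(src, tgt)
    pose = np.atleast_2d(np.asarray(pose_coords, dtype=float))
    return pose @ rot.T + t
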