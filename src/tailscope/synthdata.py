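"""Seeded synthetic inputs for every analysis stage.

These generators stand in for the expensive inputs of the real study — long
explicit-solvent MD ensembles of the H3 tail and engine-produced docking
poses — with constructions whose ground truth is known by design:

* peptide backbone trajectories built from ideal internal coordinates, with
  helical segments planted at chosen residues and switched on per frame by
  independent Bernoulli draws at a chosen persistence;
* an "active vs inactive" trajectory pair whose reach distributions are wide,
  overlapping, and shifted by construction (the compact euchromatin-like tail
  vs the extended heterochromatin-like tail with its stabilized L20–K27
  helix);
* toy nucleosome discs (DNA superhelix path + octamer pseudo-atom shell,
  labelled H3 anchor points, annotated binding sites) and stacked
  tetranucleosome assemblies;
* pose tables with a planted best grid cell.

Every generator is a pure function of its spec and seed: same inputs, same
bits.  No force field is involved anywhere — frames are i.i.d. conformers,
not dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geometry import nerf_place
from .chromatin import Nucleosome, NucleosomeAssembly, Site, transplant_site
from .dockstats import GridSpec, PoseTable
from .structio import H3_TAIL_SEQ, _AA3, Atom, Structure, Trajectory

__all__ = [
    "Segment",
    "PeptideGenSpec",
    "ToyNucleosomeSpec",
    "gen_peptide_trajectory",
    "gen_active_inactive_pair",
    "gen_toy_nucleosome",
    "gen_tetranucleosome",
    "gen_pose_table",
]

# ideal backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: canonical helix dihedrals (degrees)
PHI_PSI = {"alpha": (-57.0, -47.0), "three_ten": (-49.0, -26.0)}


@dataclass(frozen=True)
class Segment:
    """A planted secondary-structure segment (residue numbers inclusive)."""

    start_res: int
    end_res: int
    ss_class: str  # alpha | three_ten | coil
    persistence: float  # per-frame probability the segment is "on"

    def __post_init__(self):
        if self.start_res > self.end_res:
            raise ValueError("segment start after end")
        if self.ss_class not in ("alpha", "three_ten", "coil"):
            raise ValueError(f"unknown ss_class '{self.ss_class}'")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")


#: default planted segments: the stable N-terminal "tip" helix (T3–G12) and
#: the less persistent "middle" helix (L20–A29) of the unmodified tail.
DEFAULT_SEGMENTS = (
    Segment(3, 12, "alpha", 0.8),
    Segment(20, 29, "alpha", 0.4),
)


@dataclass(frozen=True)
class PeptideGenSpec:
    """Specification of a synthetic peptide backbone ensemble."""

    seed: int
    n_res: int = 43
    #: None selects the default tip/middle helices when they fit the peptide
    segments: tuple[Segment, ...] | None = None
    n_frames: int = 2000
    dt: float = 25.0  # ps between frames
    coil_dihedral_jitter: float = 25.0  # degrees, s.d. around the coil means
    coil_phi: float = -120.0
    coil_psi: float = 130.0
    label: str = "synthetic_peptide"

    def __post_init__(self):
        if self.n_res < 2:
            raise ValueError("need at least 2 residues")
        if self.segments is None:
            fitting = tuple(s for s in DEFAULT_SEGMENTS if s.end_res <= self.n_res)
            object.__setattr__(self, "segments", fitting)
        covered: set[int] = set()
        for s in self.segments:
            if s.start_res < 1 or s.end_res > self.n_res:
                raise ValueError(f"segment {s} outside 1..{self.n_res}")
            span = set(range(s.start_res, s.end_res + 1))
            if covered & span:
                raise ValueError("overlapping segments")
            covered |= span


def _peptide_sequence(n_res: int) -> list[str]:
    """Residue names: the H3 tail for the first 43 positions, Ala beyond."""
    seq = [(H3_TAIL_SEQ[i] if i < len(H3_TAIL_SEQ) else "A") for i in range(n_res)]
    return [_AA3[aa] for aa in seq]


def _peptide_topology(n_res: int, label: str) -> Structure:
    """Backbone + Cβ-stub topology: N, CA, C, O (+ CB except Gly) per residue."""
    names = _peptide_sequence(n_res)
    atoms = []
    for r in range(1, n_res + 1):
        for atom_name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(
                Atom(atom_name, element, r, names[r - 1], "A", (0.0, 0.0, 0.0))
            )
        if names[r - 1] != "GLY":
            atoms.append(Atom("CB", "C", r, names[r - 1], "A", (0.0, 0.0, 0.0)))
    return Structure(atoms, label=label)


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> dict[str, np.ndarray]:
    """Backbone coordinates from per-frame dihedrals.

    ``phi``/``psi`` have shape (n_frames, n_res) in radians (phi of residue 1
    and psi of the last residue only place the terminal carbonyl).  Returns
    per-atom-name arrays of shape (n_frames, n_res, 3).
    """
    f, nres = phi.shape
    omega = math.radians(OMEGA)
    a_nca = math.radians(ANGLE_N_CA_C)
    a_can = math.radians(ANGLE_CA_C_N)
    a_cnc = math.radians(ANGLE_C_N_CA)
    a_cao = math.radians(ANGLE_CA_C_O)

    n = np.empty((f, nres, 3))
    ca = np.empty((f, nres, 3))
    c = np.empty((f, nres, 3))
    o = np.empty((f, nres, 3))

    # residue 1 in a fixed local frame
    n[:, 0] = [0.0, 0.0, 0.0]
    ca[:, 0] = [BOND_N_CA, 0.0, 0.0]
    c[:, 0] = ca[:, 0] + BOND_CA_C * np.array(
        [-math.cos(a_nca), math.sin(a_nca), 0.0]
    )
    # re-place C1 honouring phi of residue 1 via a virtual previous carbonyl
    virt = np.broadcast_to(np.array([-0.5, -1.2, 0.0]), (f, 3))
    c[:, 0] = nerf_place(virt, n[:, 0], ca[:, 0], BOND_CA_C, a_nca, phi[:, 0])

    for r in range(1, nres):
        n[:, r] = nerf_place(n[:, r - 1], ca[:, r - 1], c[:, r - 1], BOND_C_N, a_can, psi[:, r - 1])
        ca[:, r] = nerf_place(ca[:, r - 1], c[:, r - 1], n[:, r], BOND_N_CA, a_cnc, np.full(f, omega))
        c[:, r] = nerf_place(c[:, r - 1], n[:, r], ca[:, r], BOND_CA_C, a_nca, phi[:, r])
    cb = np.empty((f, nres, 3))
    for r in range(nres):
        o[:, r] = nerf_place(n[:, r], ca[:, r], c[:, r], BOND_C_O, a_cao, psi[:, r] + math.pi)
        # Cβ stub off the Cα, tetrahedral branch between N and C
        cb[:, r] = nerf_place(
            c[:, r], n[:, r], ca[:, r], 1.53, math.radians(110.5),
            np.full(f, math.radians(123.0)),
        )
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _assemble_frames(topology: Structure, parts: dict[str, np.ndarray]) -> np.ndarray:
    """Order per-atom-name coordinate blocks into the topology's atom order."""
    f = parts["N"].shape[0]
    out = np.empty((f, len(topology), 3))
    for i, a in enumerate(topology.atoms):
        out[:, i] = parts[a.name][:, a.res_seq - 1]
    return out


def gen_peptide_trajectory(spec: PeptideGenSpec) -> Trajectory:
    """Backbone ensemble with planted helical segments.

    Each segment is switched on independently per frame with probability
    ``persistence``; "on" residues take canonical helix dihedrals, everything
    else draws jittered coil dihedrals.
    """
    rng = np.random.default_rng(spec.seed)
    f, nres = spec.n_frames, spec.n_res
    jit = math.radians(spec.coil_dihedral_jitter)
    phi = rng.normal(math.radians(spec.coil_phi), jit, size=(f, nres))
    psi = rng.normal(math.radians(spec.coil_psi), jit, size=(f, nres))
    for seg in spec.segments:
        if seg.ss_class == "coil":
            continue
        on = rng.random(f) < seg.persistence
        ph, ps = (math.radians(x) for x in PHI_PSI[seg.ss_class])
        sl = slice(seg.start_res - 1, seg.end_res)
        phi[on, sl] = ph
        psi[on, sl] = ps
    topo = _peptide_topology(nres, spec.label)
    frames = _assemble_frames(topo, _build_backbone(phi, psi))
    return Trajectory(topo.with_coords(frames[0]), frames, spec.dt)


def gen_active_inactive_pair(
    n_frames: int = 2000, seed: int = 0, dt: float = 25.0
) -> tuple[Trajectory, Trajectory]:
    """Compact "active-like" and extended "inactive-like" 43-mer ensembles.

    Each frame draws a global extension weight w mixing compact curled
    dihedrals (w=0) with extended ones (w=1); the active tail draws
    w ~ U(0, 0.55), the inactive w ~ U(0.35, 1) and additionally plants the
    stabilized L20–K27 α-helix at persistence 0.7.  The resulting reach
    distributions are broad and overlapping, with the inactive mean larger by
    construction.
    """
    if n_frames < 100:
        raise ValueError("need at least 100 frames for a meaningful pair")
    ss = np.random.SeedSequence(seed)
    rng_a, rng_i = (np.random.default_rng(s) for s in ss.spawn(2))
    compact = (math.radians(-70.0), math.radians(-35.0))
    extended = (math.radians(-135.0), math.radians(145.0))
    nres = 43
    jit = math.radians(10.0)

    def build(rng, w_lo, w_hi, helix_seg: Segment | None, label: str) -> Trajectory:
        w = rng.uniform(w_lo, w_hi, size=(n_frames, 1))
        phi = (1 - w) * compact[0] + w * extended[0] + rng.normal(0, jit, (n_frames, nres))
        psi = (1 - w) * compact[1] + w * extended[1] + rng.normal(0, jit, (n_frames, nres))
        if helix_seg is not None:
            on = rng.random(n_frames) < helix_seg.persistence
            ph, ps = (math.radians(x) for x in PHI_PSI[helix_seg.ss_class])
            sl = slice(helix_seg.start_res - 1, helix_seg.end_res)
            phi[on, sl] = ph
            psi[on, sl] = ps
        topo = _peptide_topology(nres, label)
        frames = _assemble_frames(topo, _build_backbone(phi, psi))
        return Trajectory(topo.with_coords(frames[0]), frames, dt)

    active = build(rng_a, 0.0, 0.55, None, "active_like")
    inactive = build(rng_i, 0.35, 1.0, Segment(20, 27, "alpha", 0.7), "inactive_like")
    return active, inactive


# ---------------------------------------------------------------------------
# Toy nucleosomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyNucleosomeSpec:
    """Geometry of a pseudo-atom nucleosome disc (superhelix axis along z)."""

    dna_radius: float = 42.0  # Å
    dna_turns: float = 1.65
    pitch: float = 25.9  # Å rise per superhelical turn
    n_dna_points: int = 147  # one pseudo-atom per wrapped base pair
    octamer_radius: float = 30.0
    n_octamer_points: int = 80
    #: H3 anchor (P43 Cα) offsets in the disc frame, one per H3 copy
    anchor_offsets: tuple[tuple[float, float, float], ...] = (
        (38.0, 0.0, -12.0),
        (-38.0, 0.0, 12.0),
    )
    #: annotated sites in the disc frame
    tip_site_offset: tuple[float, float, float] = (30.0, 20.0, 15.0)
    acidic_patch_offset: tuple[float, float, float] = (0.0, 10.0, 26.0)

    def __post_init__(self):
        if min(self.dna_radius, self.pitch, self.octamer_radius) <= 0:
            raise ValueError("dimensions must be positive")


_OCTAMER_CHAINS = "ABCDEFGH"  # H3, H4, H2A, H2B ×2 in a 1KX5-like labelling


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    ga = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return radius * np.stack([r * np.cos(ga * i), r * np.sin(ga * i), z], axis=1)


def _toy_nucleosome_structure(spec: ToyNucleosomeSpec, nuc_id: str) -> Structure:
    atoms = []
    # DNA superhelix path (chain I), one phosphate pseudo-atom per point
    t = np.linspace(0.0, 1.0, spec.n_dna_points)
    theta = 2.0 * math.pi * spec.dna_turns * (t - 0.5)
    z_span = spec.dna_turns * spec.pitch
    if spec.dna_turns > 0:
        x = spec.dna_radius * np.cos(theta)
        y = spec.dna_radius * np.sin(theta)
        z = z_span * (t - 0.5)
    else:  # degenerate: straight segment along x
        x = spec.dna_radius * (2 * t - 1)
        y = np.zeros_like(t)
        z = np.zeros_like(t)
    # per point: one phosphorus plus a phosphate oxygen slightly inward, so
    # the DNA surface offers hydrogen-bond acceptors
    shrink = (spec.dna_radius - 1.5) / spec.dna_radius
    for k in range(spec.n_dna_points):
        atoms.append(
            Atom("P", "P", k + 1, "DA", "I", (float(x[k]), float(y[k]), float(z[k])))
        )
        atoms.append(
            Atom("O1P", "O", k + 1, "DA", "I",
                 (float(x[k] * shrink), float(y[k] * shrink), float(z[k])))
        )
    # octamer pseudo-atom shell, chains A..H by index block
    shell = _fibonacci_sphere(spec.n_octamer_points, spec.octamer_radius)
    per_chain = max(1, spec.n_octamer_points // len(_OCTAMER_CHAINS))
    for k, p in enumerate(shell):
        chain = _OCTAMER_CHAINS[min(k // per_chain, len(_OCTAMER_CHAINS) - 1)]
        atoms.append(Atom("CA", "C", k + 1, "GLY", chain, tuple(float(v) for v in p)))
    # H3 P43 anchor atoms on the two H3 chains (A and E in 1KX5 labelling);
    # res_seq 200+k keeps them clear of the pseudo-atom numbering
    for k, off in enumerate(spec.anchor_offsets):
        chain = "A" if k == 0 else "E"
        atoms.append(Atom("CA", "C", 200 + k, "PRO", chain, tuple(float(v) for v in off)))
    return Structure(atoms, label=nuc_id)


def gen_toy_nucleosome(
    spec: ToyNucleosomeSpec = ToyNucleosomeSpec(), nuc_id: str = "N0", stack_id: str = "S0"
) -> NucleosomeAssembly:
    """Single toy nucleosome with anchors and annotated sites."""
    structure = _toy_nucleosome_structure(spec, nuc_id)
    anchors = [np.array(off, dtype=float) for off in spec.anchor_offsets]
    sites = [
        Site(f"{nuc_id}_tip_site", nuc_id, np.array([spec.tip_site_offset]), "tip_binding_site"),
        Site(f"{nuc_id}_acidic_patch", nuc_id, np.array([spec.acidic_patch_offset]), "acidic_patch"),
    ]
    nuc = Nucleosome(id=nuc_id, stack_id=stack_id, structure=structure, anchors=anchors)
    return NucleosomeAssembly([nuc], sites)


def gen_tetranucleosome(
    spec: ToyNucleosomeSpec = ToyNucleosomeSpec(),
    stack_separation: float = 60.0,
    nucleosome_spacing: float = 160.0,
) -> NucleosomeAssembly:
    """Two stacks × two nucleosomes, sites transplanted onto every copy.

    ``stack_separation`` is the centre-to-centre rise within a stack (z),
    ``nucleosome_spacing`` the lateral offset between the two stacks (x).
    Anchors and annotated sites are mapped onto each placed nucleosome with
    the same core-superposition transplant used for real structures.
    """
    if stack_separation <= 0 or nucleosome_spacing <= 0:
        raise ValueError("spacings must be positive")
    base = gen_toy_nucleosome(spec)
    base_struct = base.nucleosomes[0].structure
    placements = {
        ("N0", "S0"): np.array([0.0, 0.0, 0.0]),
        ("N1", "S0"): np.array([0.0, 0.0, stack_separation]),
        ("N2", "S1"): np.array([nucleosome_spacing, 0.0, 0.0]),
        ("N3", "S1"): np.array([nucleosome_spacing, 0.0, stack_separation]),
    }
    nucleosomes, sites = [], []
    for (nid, sid), shift in placements.items():
        moved = base_struct.with_coords(base_struct.coords + shift, label=nid)
        anchors = [
            transplant_site(a, base_struct, moved)[0] for a in base.nucleosomes[0].anchors
        ]
        nucleosomes.append(Nucleosome(id=nid, stack_id=sid, structure=moved, anchors=anchors))
        for s in base.sites:
            sites.append(
                Site(
                    site_id=s.site_id.replace("N0", nid),
                    nucleosome_id=nid,
                    coords=transplant_site(s.coords, base_struct, moved),
                    kind=s.kind,
                )
            )
    return NucleosomeAssembly(nucleosomes, sites)


# ---------------------------------------------------------------------------
# Pose tables
# ---------------------------------------------------------------------------

def gen_pose_table(
    grid: GridSpec,
    structure_labels: list[str],
    planted_best: dict[str, str],
    seed: int = 0,
    noise_sd: float = 1.5,
    margin: float = 2.0,
) -> PoseTable:
    """One best-pose energy per (structure, cell) with a planted winner.

    The planted cell's energy strictly exceeds every other cell of its
    structure by at least ``margin`` kcal/mol; all other energies are seeded
    Gaussian noise around zero.
    """
    labels = grid.labels
    for s, cell in planted_best.items():
        if cell not in labels:
            raise ValueError(f"planted cell '{cell}' not in grid")
    rng = np.random.default_rng(seed)
    rows = []
    for s in structure_labels:
        energies = rng.normal(0.0, noise_sd, size=len(labels))
        if s in planted_best:
            k = labels.index(planted_best[s])
            others = np.delete(energies, k)
            energies[k] = others.max() + margin
        for cell, e in zip(labels, energies):
            rows.append({"structure_label": s, "cell_label": cell, "binding_energy": round(float(e), 2)})
    return PoseTable(pd.DataFrame(rows))
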