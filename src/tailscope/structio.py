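"""Structure and trajectory I/O plus tail extraction and PTM annotation.

The in-memory model is deliberately light: a :class:`Structure` is an ordered
list of :class:`Atom` records, and a :class:`Trajectory` is a fixed topology
plus an ``(n_frames, n_atoms, 3)`` coordinate block.  Multi-model PDB is the
on-disk trajectory format (one MODEL per frame); reading goes through
Biopython, writing through a fixed-column formatter so coordinates round-trip
at PDB precision (3 decimals).

Post-translational modifications are annotated at the residue-name level
(e.g. LYS -> ALY for acetylation); no modified side-chain geometry is built,
because none of the downstream analyses read side-chain atoms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import (
    CongruenceError,
    ModelNotFoundError,
    PDBParseError,
    PTMPatternError,
    SelectionError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "PTMPattern",
    "H3_TAIL_SEQ",
    "BUILTIN_PATTERNS",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "extract_tail",
    "apply_ptm_pattern",
    "builtin_pattern",
    "parse_ptm_tokens",
    "load_ptm_config",
    "frame_count",
]

#: Human histone H3 N-terminal tail, residues 1-43 (the chain-A segment of a
#: 1KX5-like nucleosome used as the unmodified tail).
H3_TAIL_SEQ = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRP"

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates in Å)."""

    name: str
    element: str
    res_seq: int
    res_name: str
    chain_id: str
    coords: tuple[float, float, float]

    def __post_init__(self):
        if self.res_seq < 1:
            raise ValueError(f"res_seq must be >= 1, got {self.res_seq}")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Structure:
    """An ordered collection of atoms with a free-text label."""

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self):
        keys = [(a.chain_id, a.res_seq, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain_id, res_seq, name) in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "Structure":
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate block does not match atom count")
        atoms = [replace(a, coords=tuple(map(float, c))) for a, c in zip(self.atoms, xyz)]
        return Structure(atoms, self.label if label is None else label)

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_seq, res_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int]] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            k = (a.chain_id, a.res_seq)
            if k not in seen:
                seen[k] = a.res_name
                order.append(k)
        return [(c, r, seen[(c, r)]) for c, r in order]

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (a.chain_id, a.res_seq, a.name) == (chain_id, res_seq, name):
                return i
        raise SelectionError(f"atom {chain_id}/{res_seq}/{name} not found")

    def ca_indices(self, res_range: tuple[int, int] | None = None) -> list[int]:
        """Indices of Cα atoms, optionally restricted to a res_seq range."""
        out = []
        for i, a in enumerate(self.atoms):
            if a.name != "CA":
                continue
            if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
                continue
            out.append(i)
        if not out:
            raise SelectionError(f"no Cα atoms in selection {res_range}")
        return out


@dataclass
class Trajectory:
    """Fixed-topology ordered frames with a time step in ps."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    dt: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError("frames must be (n_frames, n_atoms, 3) congruent with topology")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps."""
        return np.arange(self.n_frames) * self.dt

    def frame_structure(self, i: int, label: str | None = None) -> Structure:
        if not 0 <= i < self.n_frames:
            raise SelectionError(f"frame {i} out of range (0..{self.n_frames - 1})")
        lbl = label if label is not None else f"{self.topology.label} frame {i} ({i * self.dt:g} ps)"
        return self.topology.with_coords(self.frames[i], label=lbl)


# ---------------------------------------------------------------------------
# PTM patterns
# ---------------------------------------------------------------------------

#: modification code -> (compatible native 3-letter codes, replacement code)
_MOD_TABLE = {
    "me2": ({"LYS"}, "MLY"),
    "me3": ({"LYS"}, "M3L"),
    "ac": ({"LYS"}, "ALY"),
    "ph": ({"SER", "THR"}, None),  # SER->SEP, THR->TPO
    "to_ala": (None, "ALA"),
    "to_gly": (None, "GLY"),
}


@dataclass(frozen=True)
class PTMPattern:
    """A named set of residue-level modifications, e.g. the 'active' isoform."""

    name: str
    mods: tuple[tuple[int, str], ...]

    def __post_init__(self):
        seen = set()
        for res_seq, code in self.mods:
            if code not in _MOD_TABLE:
                raise PTMPatternError(f"unknown modification code '{code}'")
            if res_seq in seen:
                raise PTMPatternError(f"residue {res_seq} modified more than once")
            seen.add(res_seq)


def _all_of(seq: str, letter: str, code: str) -> tuple[tuple[int, str], ...]:
    return tuple((i + 1, code) for i, aa in enumerate(seq) if aa == letter)


#: The isoform patterns used throughout: euchromatin-associated ("active"),
#: heterochromatin-associated ("inactive"), fully acetylated lysines, and the
#: all-Ala / all-Gly helix-propensity controls.
BUILTIN_PATTERNS: dict[str, PTMPattern] = {
    "unmodified": PTMPattern("unmodified", ()),
    "active": PTMPattern("active", ((4, "me3"), (36, "me3"), (9, "ac"), (14, "ac"))),
    "inactive": PTMPattern("inactive", ((9, "me2"), (27, "me2"), (10, "ph"), (28, "ph"))),
    "hyperacetylated": PTMPattern("hyperacetylated", _all_of(H3_TAIL_SEQ, "K", "ac")),
    "ala_ctrl": PTMPattern("ala_ctrl", tuple((i + 1, "to_ala") for i in range(len(H3_TAIL_SEQ)))),
    "gly_ctrl": PTMPattern("gly_ctrl", tuple((i + 1, "to_gly") for i in range(len(H3_TAIL_SEQ)))),
}


def builtin_pattern(name: str) -> PTMPattern:
    try:
        return BUILTIN_PATTERNS[name]
    except KeyError:
        raise PTMPatternError(
            f"unknown isoform '{name}'; known: {sorted(BUILTIN_PATTERNS)}"
        ) from None


def parse_ptm_tokens(name: str, tokens: list[str]) -> PTMPattern:
    """Build a pattern from ``"K9:ac"``-style tokens.

    The leading letter is checked against the H3 tail sequence when the
    residue number falls inside it.
    """
    mods = []
    for tok in tokens:
        try:
            restok, code = tok.split(":")
            letter, num = restok[0], int(restok[1:])
        except (ValueError, IndexError):
            raise PTMPatternError(f"malformed PTM token '{tok}' (expected e.g. 'K9:ac')") from None
        if 1 <= num <= len(H3_TAIL_SEQ) and H3_TAIL_SEQ[num - 1] != letter.upper():
            raise PTMPatternError(
                f"token '{tok}': H3 residue {num} is {H3_TAIL_SEQ[num - 1]}, not {letter.upper()}"
            )
        mods.append((num, code))
    return PTMPattern(name, tuple(mods))


def load_ptm_config(path: str | Path) -> dict[str, PTMPattern]:
    """Load isoform definitions from a YAML/JSON mapping name -> token list."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PTMPatternError(f"PTM config {path} must map isoform names to token lists")
    return {name: parse_ptm_tokens(name, tokens or []) for name, tokens in raw.items()}


def apply_ptm_pattern(s: Structure, p: PTMPattern) -> Structure:
    """Rewrite residue names according to a PTM pattern; coordinates untouched."""
    res_names = {(c, r): n for c, r, n in s.residues()}
    present = {r for (_, r) in res_names}
    rename: dict[int, str] = {}
    for res_seq, code in p.mods:
        if res_seq not in present:
            raise PTMPatternError(f"pattern '{p.name}' targets absent residue {res_seq}")
        native = next(n for (c, r), n in res_names.items() if r == res_seq)
        allowed, new_name = _MOD_TABLE[code]
        if allowed is not None and native not in allowed:
            raise PTMPatternError(
                f"pattern '{p.name}': cannot apply '{code}' to {native}{res_seq}"
            )
        if code == "ph":
            new_name = "SEP" if native == "SER" else "TPO"
        rename[res_seq] = new_name
    atoms = [
        replace(a, res_name=rename[a.res_seq]) if a.res_seq in rename else a
        for a in s.atoms
    ]
    return Structure(atoms, label=f"{s.label}|{p.name}" if s.label else p.name)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _convert_model(model, path) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.id[2].strip():
                # insertion codes are not expected in these inputs
                raise PDBParseError(
                    f"{path}: insertion code '{residue.id[2]}' at residue "
                    f"{chain.id}/{residue.id[1]} is not supported"
                )
            for atom in residue.get_unpacked_list():
                altloc = atom.get_altloc().strip()
                if altloc not in ("", "A"):
                    raise PDBParseError(
                        f"{path}: altloc '{altloc}' at atom {atom.get_name()} of "
                        f"residue {chain.id}/{residue.id[1]}; only ''/'A' accepted"
                    )
                res_seq = residue.id[1]
                if res_seq < 1:
                    raise PDBParseError(
                        f"{path}: non-positive residue number {res_seq} in chain {chain.id}"
                    )
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=(atom.element or "").strip() or atom.get_name()[0],
                        res_seq=res_seq,
                        res_name=residue.get_resname().strip(),
                        chain_id=chain.id if chain.id.strip() else "A",
                        coords=tuple(float(x) for x in atom.coord),
                    )
                )
    return atoms


def _parse_pdb(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise PDBParseError(f"{path}: malformed record ({exc})") from exc
    models = list(structure)
    if not models or all(len(list(m.get_atoms())) == 0 for m in models):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return models


def read_structure(path: str | Path, model_index: int = 1) -> Structure:
    """Read one MODEL of a PDB file (1-based ``model_index``, as in MODEL serials)."""
    models = _parse_pdb(path)
    if not 1 <= model_index <= len(models):
        raise ModelNotFoundError(
            f"{path}: model {model_index} not found ({len(models)} model(s))"
        )
    atoms = _convert_model(models[model_index - 1], path)
    return Structure(atoms, label=Path(path).stem)


def read_trajectory(path: str | Path, dt: float) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL)."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    models = _parse_pdb(path)
    first = _convert_model(models[0], path)
    topo = Structure(first, label=Path(path).stem)
    keys0 = [(a.chain_id, a.res_seq, a.name) for a in first]
    frames = np.empty((len(models), len(first), 3), dtype=float)
    frames[0] = [a.coords for a in first]
    for mi, model in enumerate(models[1:], start=1):
        atoms = _convert_model(model, path)
        keys = [(a.chain_id, a.res_seq, a.name) for a in atoms]
        if keys != keys0:
            raise CongruenceError(
                f"{path}: model {mi + 1} has {len(atoms)} atoms / different ordering "
                f"than model 1 ({len(first)} atoms)"
            )
        frames[mi] = [a.coords for a in atoms]
    return Trajectory(topo, frames, dt)


_STANDARD_RES = set(_AA3.values())


def _format_atom_line(serial: int, a: Atom) -> str:
    record = "ATOM" if a.res_name in _STANDARD_RES else "HETATM"
    name = a.name
    if len(name) < 4:
        name = f" {name:<3s}" if len(a.element) == 1 else f"{name:<4s}"
    x, y, z = a.coords
    return (
        f"{record:<6s}{serial:>5d} {name:4s} {a.res_name:>3s} {a.chain_id:1s}"
        f"{a.res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(path: str | Path, s: Structure) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(s.atoms, start=1):
            fh.write(_format_atom_line(i, a) + "\n")
        fh.write("END\n")


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            xyz = traj.frames[f]
            for i, a in enumerate(traj.topology.atoms, start=1):
                fh.write(_format_atom_line(i, replace(a, coords=tuple(xyz[i - 1]))) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections and bookkeeping
# ---------------------------------------------------------------------------

def extract_tail(s: Structure, chain_id: str, n_residues: int) -> Structure:
    """First ``n_residues`` residues of a chain as a new single-chain structure."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    chain_res = s.residues(chain_id)
    if not chain_res:
        raise SelectionError(f"chain '{chain_id}' not found")
    if len(chain_res) < n_residues:
        raise SelectionError(
            f"chain '{chain_id}' has only {len(chain_res)} residues, need {n_residues}"
        )
    keep = {r for (_, r, _) in chain_res[:n_residues]}
    atoms = [a for a in s.atoms if a.chain_id == chain_id and a.res_seq in keep]
    return Structure(atoms, label=f"{s.label}:{chain_id}1-{n_residues}")


def frame_count(duration_ns: float, dt_ps: float) -> int:
    """Number of saved time points for a run of ``duration_ns`` sampled every ``dt_ps``."""
    if duration_ns <= 0 or dt_ps <= 0:
        raise ValueError("duration and dt must be positive")
    return int(math.floor(duration_ns * 1000.0 / dt_ps))
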