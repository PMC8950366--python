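"""Structure and trajectory I/O for protein–ligand complexes.

Reads and writes single-model PDB files (:func:`read_pdb` / :func:`write_pdb`)
and multi-model PDB trajectories (:func:`read_model_trajectory` /
:func:`write_model_trajectory`), and resolves the two atoms every distance
measurement in this package hangs on: the heme iron of the CYP cofactor and
the ligand atom at which the metabolic reaction occurs.

Coordinates are kept in Å internally (the PDB native unit); distance-series
code converts to nm at the reporting boundary. Residues keep their author
numbering (``res_seq``) throughout — mutation positions such as 445 are
interpreted in that numbering, with no renumbering anywhere.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .errors import PDBParseError, StructureError

logger = logging.getLogger(__name__)

#: Residue names recognised as heme cofactors when locating the iron.
HEME_RESIDUES = frozenset({"HEM", "HEC", "HEA", "HEB"})

_TWO_LETTER_ELEMENTS = frozenset({
    "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "NI", "CO", "CA",
})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, mirroring the fields of a PDB coordinate record."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")


@dataclass
class Structure:
    """An ordered set of atoms (single conformation) with a free-text label."""

    atoms: list[AtomRecord]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """Coordinates as an (n_atoms, 3) float array in Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """A structure plus per-frame coordinates at a fixed time step.

    ``frames[0]`` need not equal ``structure.coords()`` numerically (the
    structure is the topology carrier), but the atom count must match.
    """

    structure: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) in Å
    dt_ps: float = 10.0
    t0_ps: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n_frames, n_atoms, 3) array")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"structure atom count {self.structure.n_atoms}"
            )
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def times_ps(self) -> np.ndarray:
        return self.t0_ps + self.dt_ps * np.arange(self.n_frames)


@dataclass(frozen=True)
class LigandSpec:
    """Names the ligand residue and its reactive atom (the site of metabolism)."""

    res_name: str
    reactive_atom_name: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.res_name or not self.reactive_atom_name:
            raise ValueError("res_name and reactive_atom_name must be non-empty")


class ChainSequence(NamedTuple):
    """One-letter sequence of a chain plus the author number of its first residue."""

    seq: str
    offset: int


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _validate_coordinate_lines(lines: Sequence[str], path: str) -> None:
    """Fail fast on malformed fixed-width ATOM/HETATM records, naming the line."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(
                f"{path}: line {lineno}: coordinate record shorter than 54 columns"
            )
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"{path}: line {lineno}: malformed coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None


def _model_atom_counts(lines: Sequence[str]) -> list[int]:
    """Atom counts per MODEL block (single implicit model if no MODEL lines)."""
    counts: list[int] = []
    in_model = False
    saw_model = False
    for line in lines:
        if line.startswith("MODEL"):
            saw_model = True
            in_model = True
            counts.append(0)
        elif line.startswith("ENDMDL"):
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            if not saw_model:
                saw_model = True  # implicit single model
                counts.append(0)
                in_model = True
            if in_model:
                counts[-1] += 1
    return counts


def _guess_element(atom_name: str, hetero: bool) -> str:
    name = "".join(c for c in atom_name if c.isalpha()).upper()
    if not name:
        return "X"
    if hetero and name[:2] in _TWO_LETTER_ELEMENTS:
        return name[:2]
    return name[0]


def _atom_array_to_structure(arr: AtomArray, label: str) -> Structure:
    atoms = []
    serials = getattr(arr, "atom_id", None)
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        hetero = bool(arr.hetero[i])
        if not element:
            element = _guess_element(str(arr.atom_name[i]), hetero)
        atoms.append(
            AtomRecord(
                serial=int(serials[i]) if serials is not None else i + 1,
                name=str(arr.atom_name[i]),
                element=element,
                res_name=str(arr.res_name[i]),
                res_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                xyz=tuple(float(x) for x in arr.coord[i]),
                hetero=hetero,
            )
        )
    return Structure(atoms=atoms, id=label)


def _structure_to_atom_array(s: Structure, coords: np.ndarray | None = None) -> AtomArray:
    n = s.n_atoms
    arr = AtomArray(n)
    arr.coord = s.coords() if coords is None else np.asarray(coords, dtype=float)
    arr.chain_id = np.array([a.chain_id for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.res_seq for a in s.atoms], dtype=int)
    arr.res_name = np.array([a.res_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element for a in s.atoms], dtype="U2")
    arr.hetero = np.array([a.hetero for a in s.atoms], dtype=bool)
    arr.set_annotation("atom_id", np.array([a.serial for a in s.atoms], dtype=int))
    return arr


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    Multi-model files are rejected with a pointer to
    :func:`read_model_trajectory`; malformed fixed-width records raise
    :class:`~hemedist.errors.PDBParseError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    _validate_coordinate_lines(lines, str(path))
    n_models = sum(1 for ln in lines if ln.startswith("MODEL"))
    if n_models > 1:
        raise PDBParseError(
            f"{path}: contains {n_models} MODEL blocks; "
            "use read_model_trajectory for trajectories"
        )
    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    try:
        pdb_file = PDBFile.read(io.StringIO(text))
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises plain ValueError subclasses
        raise PDBParseError(f"{path}: {exc}") from exc
    return _atom_array_to_structure(arr, label=path.stem)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    pdb_file = PDBFile()
    pdb_file.set_structure(_structure_to_atom_array(s))
    pdb_file.write(str(path))


def read_model_trajectory(
    path: str | Path, dt_ps: float = 10.0, t0_ps: float = 0.0
) -> Trajectory:
    """Read a multi-model PDB file as a :class:`Trajectory`.

    Frames are ordered by MODEL number; the topology is taken from the first
    model. A single-model file yields a one-frame trajectory. ``dt_ps``
    defaults to 10 ps, under which a 50 ns run spans 5000 frames.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    _validate_coordinate_lines(lines, str(path))
    counts = _model_atom_counts(lines)
    if not counts:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise PDBParseError(
            f"{path}: model {bad} has {counts[bad - 1]} atoms, "
            f"expected {counts[0]} (atom count must be constant across models)"
        )
    try:
        pdb_file = PDBFile.read(io.StringIO(text))
        stack = pdb_file.get_structure(model=None, extra_fields=["atom_id"])
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if isinstance(stack, AtomArray):  # pragma: no cover - biotite always stacks
        stack = stack.reshape((1,) + stack.shape)
    structure = _atom_array_to_structure(stack[0], label=path.stem)
    return Trajectory(
        structure=structure, frames=np.array(stack.coord), dt_ps=dt_ps, t0_ps=t0_ps
    )


def write_model_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    template = _structure_to_atom_array(traj.structure)
    stack = AtomArrayStack(traj.n_frames, traj.structure.n_atoms)
    for name in template.get_annotation_categories():
        stack.set_annotation(name, template.get_annotation(name))
    stack.coord = traj.frames
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def find_heme_iron(s: Structure) -> int:
    """Index of the single Fe atom inside a heme residue (HEM/HEC/HEA/HEB).

    This atom anchors every distance measurement in the pipeline. Zero or
    multiple candidate irons raise :class:`~hemedist.errors.StructureError`;
    with multiple hemes the caller must disambiguate explicitly.
    """
    hits = [
        i
        for i, a in enumerate(s.atoms)
        if a.element.upper() == "FE" and a.res_name.upper() in HEME_RESIDUES
    ]
    if not hits:
        raise StructureError(f"structure {s.id!r}: no heme iron (Fe in HEM/HEC/HEA/HEB) found")
    if len(hits) > 1:
        serials = [s.atoms[i].serial for i in hits]
        raise StructureError(
            f"structure {s.id!r}: {len(hits)} heme irons found (serials {serials}); "
            "disambiguate via configuration"
        )
    return hits[0]


def select_reactive_atom(s: Structure, lig: LigandSpec) -> int:
    """Index of the ligand's reactive atom (``lig.reactive_atom_name`` within
    the unique residue named ``lig.res_name``)."""
    hits = [
        i
        for i, a in enumerate(s.atoms)
        if a.res_name == lig.res_name and a.name == lig.reactive_atom_name
    ]
    if len(hits) != 1:
        raise StructureError(
            f"structure {s.id!r}: expected exactly one atom "
            f"{lig.reactive_atom_name!r} in residue {lig.res_name!r}, "
            f"found {len(hits)}"
        )
    return hits[0]


def select_atoms(
    s: Structure,
    *,
    chain_id: str | None = None,
    res_name: str | None = None,
    atom_name: str | None = None,
    hetero: bool | None = None,
) -> np.ndarray:
    """Indices of atoms matching all given field filters (None = any)."""
    idx = [
        i
        for i, a in enumerate(s.atoms)
        if (chain_id is None or a.chain_id == chain_id)
        and (res_name is None or a.res_name == res_name)
        and (atom_name is None or a.name == atom_name)
        and (hetero is None or a.hetero == hetero)
    ]
    return np.array(idx, dtype=int)


def calpha_indices(s: Structure) -> np.ndarray:
    """Indices of protein C-alpha atoms (non-hetero CA)."""
    return select_atoms(s, atom_name="CA", hetero=False)


def extract_sequence(s: Structure, chain: str) -> ChainSequence:
    """One-letter sequence of a chain's polymer residues, with numbering offset.

    HETATM residues (cofactors, ligands) are excluded. Residues are ordered by
    ``res_seq``; numbering gaps do not insert placeholders — the first residue
    number is returned as ``offset`` so that author position ``p`` maps to
    string index ``p - offset``. Non-standard residues map to ``"X"``.
    """
    residues: dict[int, str] = {}
    found_chain = False
    for a in s.atoms:
        if a.chain_id != chain:
            continue
        found_chain = True
        if a.hetero:
            continue
        residues.setdefault(a.res_seq, a.res_name)
    if not found_chain:
        raise StructureError(f"structure {s.id!r}: chain {chain!r} not found")
    if not residues:
        raise StructureError(f"structure {s.id!r}: chain {chain!r} has no polymer residues")
    ordered = sorted(residues)
    letters = []
    for res_seq in ordered:
        try:
            letters.append(ProteinSequence.convert_letter_3to1(residues[res_seq]))
        except Exception:
            letters.append("X")
    return ChainSequence(seq="".join(letters), offset=ordered[0])
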