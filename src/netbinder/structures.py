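"""Protein/ligand structure I/O and geometry primitives.

Structures are ordered collections of :class:`AtomRecord` read from PDB files
(single model, multi-model, or a directory of same-topology files).  All
coordinates are in Ångström; masses in atomic mass units.  Parsing and
serialisation are delegated to :mod:`biotite.structure.io.pdb`; this module
adds atom selection, mass assignment, centers of mass and pairwise distances
— the geometric quantities every downstream stage (pooling, clustering,
network building, trajectory analysis) is built on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "Structure",
    "PoseEnsemble",
    "ATOMIC_MASSES",
    "read_structure",
    "read_pose_ensemble",
    "write_structure",
    "write_pose_ensemble",
    "center_of_mass",
    "atom_pair_distance",
    "parse_selector",
    "select_atoms",
]

#: Standard atomic masses (IUPAC 2021 abridged), amu.  Unknown elements are a
#: hard error at read time rather than silently defaulted.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "LI": 6.94, "BE": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "NA": 22.990,
    "MG": 24.305, "AL": 26.982, "SI": 28.085, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, with identity, coordinates and mass."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    coords: tuple[float, float, float]
    mass: float
    insertion_code: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite coordinates")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial} {self.name!r}: non-positive mass")


class Structure:
    """An ordered list of atoms with cached coordinate/mass arrays.

    Parameters
    ----------
    atoms : sequence of AtomRecord
        Must be non-empty.
    label : str
        Free-form identifier (file stem, model number, ...).
    """

    def __init__(self, atoms: Sequence[AtomRecord], label: str = "") -> None:
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure must contain at least one atom")
        self.atoms: list[AtomRecord] = atoms
        self.label = label
        self._coords: np.ndarray | None = None
        self._masses: np.ndarray | None = None
        self._heavy: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {self.label!r}: {len(self)} atoms>"

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of coordinates, Å."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def masses(self) -> np.ndarray:
        if self._masses is None:
            self._masses = np.array([a.mass for a in self.atoms], dtype=float)
        return self._masses

    @property
    def heavy_mask(self) -> np.ndarray:
        if self._heavy is None:
            self._heavy = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        return self._heavy

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask]

    def center_of_mass(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return center_of_mass(atoms)

    def translated(self, shift: Sequence[float], label: str | None = None) -> "Structure":
        """A copy with all coordinates shifted by ``shift`` (Å)."""
        s = np.asarray(shift, dtype=float)
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                       a.chain, tuple(np.asarray(a.coords) + s), a.mass, a.insertion_code)
            for a in self.atoms
        ]
        return Structure(atoms, label if label is not None else self.label)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float],
                    label: str | None = None) -> "Structure":
        """A copy under the rigid motion x ↦ R·x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = self.coords @ R.T + t
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                       a.chain, tuple(c), a.mass, a.insertion_code)
            for a, c in zip(self.atoms, new)
        ]
        return Structure(atoms, label if label is not None else self.label)

    def select(self, chain: str | None = None, residue_id: int | None = None,
               residue_name: str | None = None, name: str | None = None,
               heavy_only: bool = False) -> list[AtomRecord]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if residue_id is not None and a.residue_id != residue_id:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if name is not None and a.name != name:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(a)
        return out


@dataclass
class PoseEnsemble:
    """An ordered pose collection with identical atom ordering across poses.

    ``frame_times`` (ns), when present, must be strictly increasing and align
    one-to-one with ``poses``.
    """

    poses: list[Structure]
    frame_times: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.poses:
            ref = self.poses[0].atom_names
            n = len(self.poses[0])
            for i, p in enumerate(self.poses):
                if len(p) != n or p.atom_names != ref:
                    raise ValueError(
                        f"pose {i} ({p.label!r}) has inconsistent atoms "
                        f"({len(p)} vs {n} expected)"
                    )
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.poses):
                raise ValueError("frame_times length does not match pose count")
            if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ValueError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i: int) -> Structure:
        return self.poses[i]


# ---------------------------------------------------------------------------
# element / mass assignment

_TWO_LETTER = {k for k in ATOMIC_MASSES if len(k) == 2}


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Guess the element from a PDB atom name.

    Hydrogen names may start with a digit ("1HB").  Two-letter elements are
    only accepted when the residue itself looks like an ion/metal entry
    (residue name equals the element), so " CA " in ALA stays carbon while
    "CA" in residue "CA" is calcium.
    """
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name; cannot infer element")
    core = stripped.lstrip("0123456789")
    if not core:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = core[:2].upper()
    if two in _TWO_LETTER and residue_name.strip().upper() == two:
        return two.capitalize()
    return core[0].upper()


def _mass_for(element: str, context: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no atomic mass for element {element!r} ({context})") from None


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)


def _file_has_element_column(pdb) -> bool:
    for line in pdb.lines:
        if line.startswith(("ATOM", "HETATM")) and line[76:78].strip():
            return True
    return False


def _atom_array_to_structure(arr, label: str, infer_all: bool = False) -> Structure:
    elements = np.asarray(arr.element, dtype=object)
    names = arr.atom_name
    res_names = arr.res_name
    for i in range(arr.array_length()):
        # when the file carries no element columns, name-based inference
        # (residue-aware, so " CA " in ALA is carbon, not calcium) overrides
        # the parser's context-free guess
        if infer_all or not str(elements[i]).strip():
            elements[i] = _infer_element(str(names[i]), str(res_names[i]))
    serials = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    ins = (arr.ins_code if "ins_code" in arr.get_annotation_categories()
           else [""] * arr.array_length())
    atoms = []
    for i in range(arr.array_length()):
        el = str(elements[i]).strip().capitalize()
        atoms.append(AtomRecord(
            serial=int(serials[i]),
            name=str(names[i]).strip(),
            element=el,
            residue_name=str(res_names[i]).strip(),
            residue_id=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]).strip(),
            coords=tuple(float(x) for x in arr.coord[i]),
            mass=_mass_for(el, f"atom {serials[i]} {names[i]!r}"),
            insertion_code=str(ins[i]).strip(),
        ))
    return Structure(atoms, label=label)


def read_structure(path: str | Path, model_index: int | None = None) -> Structure:
    """Read one model of a PDB file.

    Parameters
    ----------
    path : path to a PDB file.
    model_index : 1-based model number; default: the first model.

    Missing element columns are inferred from atom names; every atom is
    assigned a standard atomic mass (unknown elements raise ``KeyError``).
    Both ATOM and HETATM records are kept; of alternate locations only the
    first ('A' or blank) is retained.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    model = 1 if model_index is None else int(model_index)
    if not 1 <= model <= n_models:
        raise ValueError(f"{path}: model {model} absent (file has {n_models})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element-guessing notice
        arr = pdb.get_structure(model=model, altloc="first", extra_fields=["atom_id"])
    return _atom_array_to_structure(arr, label=f"{path.stem}" if n_models == 1
                                    else f"{path.stem}#{model}",
                                    infer_all=not _file_has_element_column(pdb))


def read_pose_ensemble(source: str | Path,
                       frame_times: Sequence[float] | None = None) -> PoseEnsemble:
    """Read a pose ensemble from a multi-model PDB or a directory of PDBs.

    Directory files are taken in lexicographic order; all poses must share
    atom count and atom names.
    """
    from biotite.structure.io.pdb import PDBFile

    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise FileNotFoundError(f"no PDB files in {source}")
        poses = [read_structure(f) for f in files]
        label = source.name
    else:
        pdb = PDBFile.read(str(source))
        infer_all = not _file_has_element_column(pdb)
        poses = []
        for m in range(1, pdb.get_model_count() + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                arr = pdb.get_structure(model=m, altloc="first",
                                        extra_fields=["atom_id"])
            poses.append(_atom_array_to_structure(arr, label=f"{source.stem}#{m}",
                                                  infer_all=infer_all))
        label = source.stem
    times = None if frame_times is None else np.asarray(frame_times, dtype=float)
    return PoseEnsemble(poses=poses, frame_times=times, label=label)


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as struc

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = np.array([a.residue_id for a in structure.atoms])
    arr.ins_code = np.array([a.insertion_code for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.array([a.residue_name not in _STANDARD_RESIDUES
                           for a in structure.atoms])
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    return arr


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single structure as a PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


def write_pose_ensemble(ensemble: PoseEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [_structure_to_atom_array(p) for p in ensemble.poses]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# geometry


def center_of_mass(atoms: Iterable[AtomRecord] | Structure) -> np.ndarray:
    """Mass-weighted mean coordinate, Å."""
    if isinstance(atoms, Structure):
        coords, masses = atoms.coords, atoms.masses
    else:
        atoms = list(atoms)
        if not atoms:
            raise ValueError("center of mass of an empty atom list")
        coords = np.array([a.coords for a in atoms], dtype=float)
        masses = np.array([a.mass for a in atoms], dtype=float)
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


@dataclass(frozen=True)
class Selector:
    """Addresses exactly one atom: by chain/residue/atom name, by residue
    name/atom name (ligand style), or by residue id/atom name."""

    atom_name: str
    chain: str | None = None
    residue_id: int | None = None
    residue_name: str | None = None

    def matches(self, a: AtomRecord) -> bool:
        if a.name != self.atom_name:
            return False
        if self.chain is not None and a.chain != self.chain:
            return False
        if self.residue_id is not None and a.residue_id != self.residue_id:
            return False
        if self.residue_name is not None and a.residue_name != self.residue_name:
            return False
        return True

    def __str__(self) -> str:
        parts = [p for p in (self.chain,
                             str(self.residue_id) if self.residue_id is not None else None,
                             self.residue_name, self.atom_name) if p is not None]
        return ":".join(parts)


def parse_selector(text: str | Selector) -> Selector:
    """Parse ``"A:240:N"`` (chain:resid:atom), ``"240:N"`` (resid:atom) or
    ``"LIG:O1"`` (resname:atom) into a :class:`Selector`."""
    if isinstance(text, Selector):
        return text
    parts = [p.strip() for p in str(text).split(":")]
    if len(parts) == 3:
        return Selector(chain=parts[0], residue_id=int(parts[1]), atom_name=parts[2])
    if len(parts) == 2:
        first, atom = parts
        try:
            return Selector(residue_id=int(first), atom_name=atom)
        except ValueError:
            return Selector(residue_name=first, atom_name=atom)
    raise ValueError(f"cannot parse atom selector {text!r}")


def select_atoms(structure: Structure, selector: str | Selector) -> list[AtomRecord]:
    sel = parse_selector(selector)
    return [a for a in structure.atoms if sel.matches(a)]


def _select_one(structure: Structure, selector: str | Selector) -> AtomRecord:
    hits = select_atoms(structure, selector)
    if len(hits) != 1:
        raise ValueError(
            f"selector {str(parse_selector(selector))!r} matches {len(hits)} atoms "
            f"in {structure.label!r} (need exactly 1)"
        )
    return hits[0]


def atom_pair_distance(structure: Structure, sel_a: str | Selector,
                       sel_b: str | Selector) -> float:
    """Euclidean distance (Å) between the two uniquely selected atoms."""
    a = _select_one(structure, sel_a)
    b = _select_one(structure, sel_b)
    return float(np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)))


def min_pairwise_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two coordinate sets."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ValueError("empty coordinate set")
    return float(cdist(coords_a, coords_b).min())
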