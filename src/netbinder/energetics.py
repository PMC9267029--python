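"""Target–ligand intermolecular Lennard-Jones interaction energy.

The interaction energy between a ligand and its protein target is the 12-6
Lennard-Jones double sum over all intermolecular atom pairs,

    E_inter = Σ_i Σ_j  A_ij / r_ij^12  −  B_ij / r_ij^6

with A_ij = ε_ij R_ij^12, B_ij = 2 ε_ij R_ij^6, where R_ij = R_i + R_j is the
pair's minimum-energy separation and ε_ij = √(ε_i ε_j) the well depth at
equilibrium.  Per-atom parameters (R_i as Rmin/2 in Å, ε_i in kcal/mol)
follow the Amber force-field convention and are supplied through an editable
TSV table; the shipped default is element-keyed.

This is a pure van-der-Waals score: there is no electrostatic term, no
distance cutoff by default, and no solvation — it is NOT a total interaction
or binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Structure

__all__ = [
    "LJAtomParameter",
    "LJParameterTable",
    "ParametrizedStructure",
    "InteractionEnergy",
    "assign_parameters",
    "pair_lj",
    "interaction_energy",
]


@dataclass(frozen=True)
class LJAtomParameter:
    """Per-atom 12-6 parameters: ``r_min_half`` (Å, the R_i in R_ij = R_i + R_j)
    and ``epsilon`` (kcal/mol, the ε_i in ε_ij = √(ε_i ε_j))."""

    type_key: str
    r_min_half: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.r_min_half <= 0:
            raise ValueError(f"{self.type_key}: R_i must be positive")
        if self.epsilon < 0:
            raise ValueError(f"{self.type_key}: epsilon must be non-negative")


class LJParameterTable:
    """Lookup table of :class:`LJAtomParameter` keyed by element or atom name.

    ``assignment_mode`` decides which atom attribute is used as the key:
    ``"element"`` (default), ``"atom_name"``, or ``"explicit"`` (keys of the
    form ``RES:NAME``).  Lookups must resolve for every atom submitted to the
    energy engine; unresolved atoms are a hard error.
    """

    def __init__(self, entries: Mapping[str, LJAtomParameter],
                 assignment_mode: str = "element") -> None:
        if assignment_mode not in ("element", "atom_name", "explicit"):
            raise ValueError(f"unknown assignment mode {assignment_mode!r}")
        self.entries = {k.upper(): v for k, v in entries.items()}
        self.assignment_mode = assignment_mode

    def key_for(self, atom) -> str:
        if self.assignment_mode == "element":
            return atom.element.upper()
        if self.assignment_mode == "atom_name":
            return atom.name.upper()
        return f"{atom.residue_name}:{atom.name}".upper()

    def __contains__(self, key: str) -> bool:
        return key.upper() in self.entries

    def __getitem__(self, key: str) -> LJAtomParameter:
        return self.entries[key.upper()]

    @classmethod
    def from_tsv(cls, path: str | Path, assignment_mode: str = "element"
                 ) -> "LJParameterTable":
        """Read a table from TSV with columns type_key, R_i (Å), epsilon
        (kcal/mol); '#' starts a comment."""
        entries = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0].lower() == "type_key":
                continue
            if len(fields) < 3:
                raise ValueError(f"malformed LJ table line: {line!r}")
            key, r, eps = fields[0], float(fields[1]), float(fields[2])
            entries[key] = LJAtomParameter(key, r, eps)
        return cls(entries, assignment_mode)

    @classmethod
    def default(cls) -> "LJParameterTable":
        """The element-keyed table shipped with the package."""
        with resources.as_file(
            resources.files("netbinder").joinpath("data/lj_params.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class ParametrizedStructure:
    """A structure with per-atom LJ parameters bound as flat arrays."""

    structure: Structure
    r_min_half: np.ndarray  # (n,), Å
    epsilon: np.ndarray     # (n,), kcal/mol
    assignment_report: dict[int, str]  # atom serial -> matched key

    def __len__(self) -> int:
        return len(self.structure)


@dataclass(frozen=True)
class InteractionEnergy:
    value: float            # kcal/mol
    n_ligand_atoms: int
    n_target_atoms: int


def assign_parameters(structure: Structure, table: LJParameterTable,
                      overrides: Mapping[str, str] | None = None
                      ) -> ParametrizedStructure:
    """Bind an LJ parameter to every atom of ``structure``.

    ``overrides`` maps ``"RES:NAME"`` atom addresses to table keys and takes
    precedence over the table's own assignment mode.  Atoms that resolve to
    no table entry raise a ``KeyError`` naming all offenders.
    """
    overrides = {k.upper(): v for k, v in (overrides or {}).items()}
    r = np.empty(len(structure))
    eps = np.empty(len(structure))
    report: dict[int, str] = {}
    missing: list[str] = []
    for i, atom in enumerate(structure.atoms):
        addr = f"{atom.residue_name}:{atom.name}".upper()
        key = overrides.get(addr, table.key_for(atom))
        if key not in table:
            missing.append(f"{addr} (key {key!r})")
            continue
        p = table[key]
        r[i], eps[i] = p.r_min_half, p.epsilon
        report[atom.serial] = key.upper()
    if missing:
        raise KeyError(
            "no LJ parameters for atoms: " + ", ".join(missing)
        )
    return ParametrizedStructure(structure, r, eps, report)


def pair_lj(p_i: LJAtomParameter, p_j: LJAtomParameter, r: float) -> float:
    """12-6 pair energy (kcal/mol) at separation ``r`` (Å).

    The minimum is at r = R_i + R_j with value −√(ε_i ε_j); the curve crosses
    zero at R_ij / 2^(1/6).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    r_ij = p_i.r_min_half + p_j.r_min_half
    eps = np.sqrt(p_i.epsilon * p_j.epsilon)
    a = eps * r_ij**12
    b = 2.0 * eps * r_ij**6
    return float(a / r**12 - b / r**6)


def interaction_energy(ligand: ParametrizedStructure,
                       target: ParametrizedStructure,
                       cutoff: float | None = None) -> InteractionEnergy:
    """Sum the 12-6 pair energy over every ligand×target atom pair.

    No cutoff is applied unless ``cutoff`` (Å) is given, in which case pairs
    beyond it are excluded.  A coincident pair (r = 0) is singular and raises.
    """
    d = cdist(ligand.structure.coords, target.structure.coords)
    if np.any(d == 0.0):
        raise ValueError("ligand and target share an atom position (r = 0)")
    r_ij = ligand.r_min_half[:, None] + target.r_min_half[None, :]
    eps = np.sqrt(ligand.epsilon[:, None] * target.epsilon[None, :])
    q = (r_ij / d) ** 6
    e = eps * q * (q - 2.0)
    if cutoff is not None:
        e = np.where(d <= cutoff, e, 0.0)
    return InteractionEnergy(
        value=float(e.sum()),
        n_ligand_atoms=len(ligand),
        n_target_atoms=len(target),
    )
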