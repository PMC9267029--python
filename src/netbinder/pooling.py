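"""Conformation pools: per-pose annotation and filtering.

A conformation pool collects every ligand pose retained from the sampling
stage, annotated with its interaction energy E_inter (kcal/mol) and its
distance-to-destination d_D (Å) — the Euclidean distance between the pose's
center of mass and that of the crystallographic destination pose.  Two
filters prune the pool:

* contact trimming — a pose must make at least one heavy-atom contact
  (≤ 3.5 Å, inclusive) with a binding-cavity residue of the target;
* dissociation — a pose with d_D strictly greater than 30 Å has left the
  cavity and is discarded.

Both boundaries follow the conventions documented in docs/methods.md.  The
filters commute, so their application order is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energetics import LJParameterTable, assign_parameters, interaction_energy
from .structures import PoseEnsemble, Structure, center_of_mass

__all__ = [
    "PoolEntry",
    "ConformationPool",
    "compute_dD",
    "trim_by_contact",
    "filter_dissociated",
    "build_pool",
    "parse_cavity_residues",
]

CONTACT_CUTOFF = 3.5      # Å, inclusive
DISSOCIATION_CUTOFF = 30.0  # Å, strict


@dataclass
class PoolEntry:
    """One annotated pose of a conformation pool."""

    pose_index: int
    e_inter: float          # kcal/mol
    d_D: float              # Å
    source: str = ""
    retained: bool = True
    rejection_reason: str = "none"   # none | trimmed | dissociated

    def __post_init__(self) -> None:
        if self.d_D < 0:
            raise ValueError("d_D must be non-negative")
        if self.retained != (self.rejection_reason == "none"):
            raise ValueError("retained flag inconsistent with rejection_reason")


@dataclass
class ConformationPool:
    """Annotated pool plus the structures it refers to."""

    entries: list[PoolEntry]
    ensemble: PoseEnsemble
    destination: Structure
    target: Structure | None = None

    def retained_entries(self) -> list[PoolEntry]:
        return [e for e in self.entries if e.retained]

    def pose(self, entry: PoolEntry) -> Structure:
        return self.ensemble[entry.pose_index]

    @property
    def counts(self) -> dict[str, int]:
        n = len(self.entries)
        trimmed = sum(e.rejection_reason == "trimmed" for e in self.entries)
        dissoc = sum(e.rejection_reason == "dissociated" for e in self.entries)
        return {"input": n, "trimmed": trimmed, "dissociated": dissoc,
                "retained": n - trimmed - dissoc}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pose_index": [e.pose_index for e in self.entries],
                "source": [e.source for e in self.entries],
                "e_inter_kcal_mol": [e.e_inter for e in self.entries],
                "d_D_A": [e.d_D for e in self.entries],
                "retained": [e.retained for e in self.entries],
                "rejection_reason": [e.rejection_reason for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def compute_dD(pose: Structure, destination: Structure,
               heavy_only: bool = False) -> float:
    """Center-of-mass distance (Å) between a pose and the destination pose.

    Mass-weighted over all atoms by default; ``heavy_only`` drops hydrogens
    from both centers for sensitivity checks.
    """
    a = pose.center_of_mass(heavy_only=heavy_only)
    b = destination.center_of_mass(heavy_only=heavy_only)
    return float(np.linalg.norm(a - b))


def parse_cavity_residues(spec: str | Sequence) -> list[tuple[str | None, int]]:
    """Parse cavity residues from ``"A:238,A:240"`` or ``[("A", 238), 240]``
    into (chain, resid) pairs; chain ``None`` matches any chain."""
    if isinstance(spec, str):
        items: Sequence = [s.strip() for s in spec.split(",") if s.strip()]
    else:
        items = spec
    out: list[tuple[str | None, int]] = []
    for item in items:
        if isinstance(item, tuple):
            out.append((item[0], int(item[1])))
        elif isinstance(item, int):
            out.append((None, item))
        else:
            parts = str(item).split(":")
            if len(parts) == 2:
                out.append((parts[0] or None, int(parts[1])))
            elif len(parts) == 1:
                out.append((None, int(parts[0])))
            else:
                raise ValueError(f"cannot parse cavity residue {item!r}")
    if not out:
        raise ValueError("empty cavity residue list")
    return out


def _cavity_heavy_coords(target: Structure, cavity_residues) -> np.ndarray:
    pairs = parse_cavity_residues(cavity_residues)
    coords = []
    for chain, resid in pairs:
        atoms = target.select(chain=chain, residue_id=resid, heavy_only=True)
        if not atoms:
            raise ValueError(f"cavity residue {chain or '*'}:{resid} not found in target")
        coords.extend(a.coords for a in atoms)
    return np.asarray(coords, dtype=float)


def trim_by_contact(ensemble: PoseEnsemble, target: Structure,
                    cavity_residues, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Boolean retention flags: pose kept iff its minimum heavy-atom distance
    to any cavity-residue heavy atom is ≤ ``cutoff`` (inclusive)."""
    cavity = _cavity_heavy_coords(target, cavity_residues)
    flags = np.empty(len(ensemble), dtype=bool)
    for i, pose in enumerate(ensemble):
        d = cdist(pose.heavy_coords(), cavity).min()
        flags[i] = d <= cutoff
    return flags


def filter_dissociated(d_D: Sequence[float],
                       cutoff: float = DISSOCIATION_CUTOFF) -> np.ndarray:
    """Boolean retention flags: pose kept iff d_D ≤ cutoff (a pose is
    dissociated only when d_D exceeds the cutoff strictly)."""
    d = np.asarray(list(d_D), dtype=float)
    return ~(d > cutoff)


def build_pool(ensemble: PoseEnsemble,
               destination: Structure,
               target: Structure | None = None,
               params: LJParameterTable | None = None,
               cavity_residues=None,
               energies: Sequence[float] | None = None,
               contact_cutoff: float = CONTACT_CUTOFF,
               dissociation_cutoff: float = DISSOCIATION_CUTOFF,
               heavy_only_com: bool = False) -> ConformationPool:
    """Annotate every pose with E_inter and d_D and apply both filters.

    Energies come either from the LJ engine (``target`` + ``params``) or
    precomputed per pose via ``energies`` (synthetic pools attach energies
    directly).  Contact trimming runs only when ``cavity_residues`` and
    ``target`` are given.  The construction is fully deterministic.
    """
    n = len(ensemble)
    if energies is not None:
        if len(energies) != n:
            raise ValueError("energies length does not match ensemble")
        e_inter = np.asarray(list(energies), dtype=float)
    elif target is not None:
        table = params if params is not None else LJParameterTable.default()
        tgt_p = assign_parameters(target, table)
        e_inter = np.empty(n)
        for i, pose in enumerate(ensemble):
            lig_p = assign_parameters(pose, table)
            e_inter[i] = interaction_energy(lig_p, tgt_p).value
    else:
        raise ValueError("need either precomputed energies or a target with parameters")

    d_D = np.array([compute_dD(p, destination, heavy_only=heavy_only_com)
                    for p in ensemble])

    if cavity_residues is not None:
        if target is None:
            raise ValueError("contact trimming requires a target structure")
        contact_ok = trim_by_contact(ensemble, target, cavity_residues,
                                     cutoff=contact_cutoff)
    else:
        contact_ok = np.ones(n, dtype=bool)
    assoc_ok = filter_dissociated(d_D, cutoff=dissociation_cutoff)

    entries = []
    for i in range(n):
        # a pose failing both filters is labelled dissociated: leaving the
        # cavity is the stronger statement than merely losing contact
        if not assoc_ok[i]:
            reason = "dissociated"
        elif not contact_ok[i]:
            reason = "trimmed"
        else:
            reason = "none"
        entries.append(PoolEntry(
            pose_index=i,
            e_inter=float(e_inter[i]),
            d_D=float(d_D[i]),
            source=ensemble[i].label,
            retained=reason == "none",
            rejection_reason=reason,
        ))
    return ConformationPool(entries=entries, ensemble=ensemble,
                            destination=destination, target=target)
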