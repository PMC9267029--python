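"""Shared fixtures: tiny hand-built structures and pool builders."""

from __future__ import annotations

import numpy as np
import pytest

from netbinder.pooling import ConformationPool, PoolEntry
from netbinder.structures import ATOMIC_MASSES, AtomRecord, PoseEnsemble, Structure


def make_atom(serial=1, name="C1", element="C", coords=(0.0, 0.0, 0.0),
              residue_name="LIG", residue_id=1, chain="L", mass=None):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=residue_name,
        residue_id=residue_id, chain=chain, coords=tuple(float(c) for c in coords),
        mass=mass if mass is not None else ATOMIC_MASSES[element.upper()],
    )


def make_structure(specs, label="fixture"):
    """``specs``: iterable of (name, element, coords) or AtomRecord."""
    atoms = []
    for i, spec in enumerate(specs):
        if isinstance(spec, AtomRecord):
            atoms.append(spec)
        else:
            name, element, coords = spec
            atoms.append(make_atom(serial=i + 1, name=name, element=element,
                                   coords=coords))
    return Structure(atoms, label=label)


def point_pose(com, label="pose", element="C"):
    """A single-heavy-atom pose: its COM equals its only atom, and d_min
    between two such poses equals their COM distance."""
    return make_structure([("C1", element, tuple(com))], label=label)


def pool_from_points(coms, energies, destination_com=(0.0, 0.0, 0.0),
                     retained=None):
    """A ConformationPool of single-atom poses with attached energies —
    the minimal fixture for clustering logic (d_min == COM distance)."""
    coms = np.asarray(coms, dtype=float)
    dest = point_pose(destination_com, label="destination")
    poses = [point_pose(c, label=f"p{i}") for i, c in enumerate(coms)]
    ensemble = PoseEnsemble(poses=poses)
    d_dest = np.linalg.norm(coms - np.asarray(destination_com), axis=1)
    entries = []
    for i, (e, d) in enumerate(zip(energies, d_dest)):
        keep = True if retained is None else bool(retained[i])
        entries.append(PoolEntry(
            pose_index=i, e_inter=float(e), d_D=float(d), source=f"p{i}",
            retained=keep, rejection_reason="none" if keep else "trimmed",
        ))
    return ConformationPool(entries=entries, ensemble=ensemble,
                            destination=dest)


@pytest.fixture
def two_residue_structure():
    """A protein-like residue (GLY 240, chain A) next to a ligand with a
    hydroxyl oxygen — selectors and pair distances are hand-checkable."""
    return make_structure(
        [
            make_atom(1, "N", "N", (0.0, 0.0, 0.0), "GLY", 240, "A"),
            make_atom(2, "CA", "C", (1.458, 0.0, 0.0), "GLY", 240, "A"),
            make_atom(3, "C", "C", (2.0, 1.3, 0.0), "GLY", 240, "A"),
            make_atom(4, "O", "O", (1.4, 2.4, 0.0), "GLY", 240, "A"),
            make_atom(5, "OH", "O", (1.0, 2.0, 2.0), "LIG", 1, "L"),
            make_atom(6, "C1", "C", (2.2, 2.6, 2.6), "LIG", 1, "L"),
        ],
        label="complex",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
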