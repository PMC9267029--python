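"""Greedy energy-ranked clustering of a conformation pool into binding modes.

Pool entries are visited in ascending E_inter order.  The lowest-energy
conformation founds cluster 1 and becomes its representative (PM_1, the
first prerequisite binding mode).  Each subsequent conformation founds a new
cluster iff its closest heavy-atom distance d_min to EVERY existing
representative exceeds the ranking tolerance d_rnk (1.75 Å); otherwise it
joins the nearest representative within tolerance.  Because low-energy poses
are claimed first, representatives end up evenly spread through the cavity
without touching one another (pairwise d_min > d_rnk is an invariant of the
output).

The module also fits the energy slope: an ordinary least-squares line of
E_inter against d_D whose negative-going trend toward the destination is the
two-dimensional cross-section of the binding funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .pooling import ConformationPool
from .structures import Structure

__all__ = [
    "BindingMode",
    "SlopeFit",
    "min_heavy_atom_distance",
    "cluster_pool",
    "energy_slope",
    "binding_modes_to_dataframe",
]

RANKING_TOLERANCE = 1.75  # Å, d_rnk


@dataclass
class BindingMode:
    """A cluster representative: one prerequisite binding mode (PM)."""

    pm_id: int                 # 1-based rank; 1 = lowest E_inter
    representative: int        # pose index of the representative
    e_inter: float             # kcal/mol, of the representative
    d_D: float                 # Å, of the representative
    com: np.ndarray            # (3,) Å, representative center of mass
    members: list[int]         # pose indices, representative included


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of E_inter on d_D."""

    slope: float        # kcal/mol per Å
    intercept: float    # kcal/mol
    r_squared: float
    stderr: float       # standard error of the slope
    n_points: int


def min_heavy_atom_distance(pose_a: Structure, pose_b: Structure) -> float:
    """d_min: closest heavy-atom–heavy-atom distance (Å); hydrogens excluded."""
    a = pose_a.heavy_coords()
    b = pose_b.heavy_coords()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("pose without heavy atoms")
    return float(cdist(a, b).min())


def cluster_pool(pool: ConformationPool,
                 d_rnk: float = RANKING_TOLERANCE) -> list[BindingMode]:
    """Distill binding modes from the retained pool entries.

    Entries are processed by ascending E_inter (ties broken by ascending pose
    index).  An entry founds a new cluster iff d_min > ``d_rnk`` against every
    existing representative; otherwise it joins the nearest representative
    with d_min ≤ d_rnk.  Returned modes are ranked 1..K by representative
    E_inter, which equals founding order.
    """
    retained = [e for e in pool.entries if e.retained and np.isfinite(e.e_inter)]
    if not retained:
        raise ValueError("no retained pool entries to cluster")
    order = sorted(retained, key=lambda e: (e.e_inter, e.pose_index))

    rep_entries = []        # founding entries, in founding (= energy) order
    rep_heavy = []          # cached heavy-atom coords of representatives
    members: list[list[int]] = []
    for entry in order:
        coords = pool.pose(entry).heavy_coords()
        if len(coords) == 0:
            raise ValueError(f"pose {entry.pose_index} has no heavy atoms")
        if rep_heavy:
            dmins = np.array([cdist(coords, rc).min() for rc in rep_heavy])
            nearest = int(np.argmin(dmins))
            if dmins[nearest] <= d_rnk:
                members[nearest].append(entry.pose_index)
                continue
        rep_entries.append(entry)
        rep_heavy.append(coords)
        members.append([entry.pose_index])

    modes = []
    for k, (entry, mem) in enumerate(zip(rep_entries, members), start=1):
        pose = pool.pose(entry)
        modes.append(BindingMode(
            pm_id=k,
            representative=entry.pose_index,
            e_inter=entry.e_inter,
            d_D=entry.d_D,
            com=pose.center_of_mass(),
            members=sorted(mem),
        ))
    return modes


def energy_slope(points: Sequence[tuple[float, float]] | np.ndarray) -> SlopeFit:
    """Least-squares line of E_inter (y) on d_D (x).

    ``r_squared`` is the squared Pearson correlation of the two coordinates.
    Requires ≥ 2 points with non-degenerate x variance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (d_D, E_inter) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all d_D values identical; slope undefined")
    if np.ptp(y) == 0:
        # constant energy: the horizontal line fits exactly; Pearson r is
        # undefined, so report the perfect-fit limit
        return SlopeFit(slope=0.0, intercept=float(y[0]), r_squared=1.0,
                        stderr=0.0, n_points=len(x))
    fit = stats.linregress(x, y)
    return SlopeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        stderr=float(fit.stderr),
        n_points=len(x),
    )


def binding_modes_to_dataframe(modes: Sequence[BindingMode],
                               by_distance: bool = False) -> pd.DataFrame:
    """Tabulate binding modes; ``by_distance`` sorts rows by d_D without
    renumbering (a presentation-only view)."""
    df = pd.DataFrame(
        {
            "pm_id": [m.pm_id for m in modes],
            "representative_index": [m.representative for m in modes],
            "e_inter_kcal_mol": [m.e_inter for m in modes],
            "d_D_A": [m.d_D for m in modes],
            "com_x": [m.com[0] for m in modes],
            "com_y": [m.com[1] for m in modes],
            "com_z": [m.com[2] for m in modes],
            "n_members": [len(m.members) for m in modes],
        }
    )
    if by_distance:
        df = df.sort_values("d_D_A").reset_index(drop=True)
    return df


def write_binding_modes(modes: Sequence[BindingMode], pool: ConformationPool,
                        table_path: str | Path,
                        pdb_path: str | Path | None = None) -> None:
    """Write the PM table as TSV and, optionally, the representative poses as
    a multi-model PDB (one model per PM, in rank order)."""
    binding_modes_to_dataframe(modes).to_csv(table_path, sep="\t", index=False)
    if pdb_path is not None:
        from .structures import PoseEnsemble, write_pose_ensemble

        reps = [pool.ensemble[m.representative] for m in modes]
        write_pose_ensemble(PoseEnsemble(poses=reps, label="binding_modes"),
                            pdb_path)
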