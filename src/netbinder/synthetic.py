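"""Synthetic pose pools, cluster fixtures and step trajectories.

Every downstream stage (pooling, clustering, slope fitting, networking,
event detection) is testable without external structure files through the
generators here.  They emulate the statistical shape of a binding-funnel
experiment — a ligand accumulating poses in a tubular cavity whose
interaction energy falls linearly as the pose approaches the destination —
with fully known ground truth and seeded determinism:

* :func:`generate_funnel_pool` — rigid ligand copies in a tube, energies
  ``a·d_D + b + N(0, σ²)``, an optional dissociated fraction beyond 30 Å.
* :func:`generate_cluster_fixture` — K planted, well-separated pose blobs
  for testing greedy cluster recovery.
* :func:`generate_step_trajectory` — a noisy step distance series with a
  known transition time for event detection.

Energies are attached to poses directly (bypassing the Lennard-Jones
engine), which keeps clustering/slope tests independent of the energy
engine's own tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .events import DistanceSeries
from .pooling import ConformationPool, PoolEntry, build_pool
from .structures import AtomRecord, PoseEnsemble, Structure

__all__ = [
    "FunnelSpec",
    "GroundTruth",
    "ligand_template",
    "generate_funnel_pool",
    "generate_cluster_fixture",
    "generate_step_trajectory",
    "funnel_conformation_pool",
]

DISSOCIATED_MIN_DD = 32.0  # Å, where dissociated poses are parked (> 30 Å rule)
DISSOCIATED_MAX_DD = 45.0

# Hand-written rigid ligand fragment: a para-substituted phenol ring with an
# acetyl arm — 10 heavy atoms incl. one hydroxyl oxygen (OH, with hydrogen HO)
# and one carbonyl oxygen (O1), so Table-1-style selectors ("LIG:OH") work.
# Roughly centered on its center of mass; bond lengths are idealized.
_TEMPLATE_ATOMS: list[tuple[str, str, tuple[float, float, float]]] = [
    ("C1", "C", (-1.212, -0.700, 0.000)),
    ("C2", "C", (-1.212, 0.700, 0.000)),
    ("C3", "C", (0.000, 1.400, 0.000)),
    ("C4", "C", (1.212, 0.700, 0.000)),
    ("C5", "C", (1.212, -0.700, 0.000)),
    ("C6", "C", (0.000, -1.400, 0.000)),
    ("OH", "O", (0.000, 2.760, 0.000)),
    ("C7", "C", (0.000, -2.910, 0.000)),
    ("O1", "O", (1.050, -3.530, 0.000)),
    ("C8", "C", (-1.285, -3.516, 0.520)),
    ("HO", "H", (0.864, 3.163, 0.305)),
    ("H2", "H", (-2.150, 1.240, 0.000)),
    ("H5", "H", (2.150, -1.240, 0.000)),
]

_ELEMENT_MASS = {"C": 12.011, "O": 15.999, "H": 1.008}


def ligand_template(label: str = "LIG") -> Structure:
    """The rigid synthetic ligand, centered at its center of mass."""
    atoms = [
        AtomRecord(serial=i + 1, name=name, element=el, residue_name="LIG",
                   residue_id=1, chain="L", coords=xyz,
                   mass=_ELEMENT_MASS[el])
        for i, (name, el, xyz) in enumerate(_TEMPLATE_ATOMS)
    ]
    s = Structure(atoms, label=label)
    return s.translated(-s.center_of_mass(), label=label)


@dataclass(frozen=True)
class FunnelSpec:
    """Generative conditions of a synthetic funnel pool.

    The tube runs along +x from the destination at the origin; pose centers
    of mass sit inside the tube, and each pose's energy is a linear function
    of its distance to the destination plus Gaussian noise.
    """

    n_poses: int = 500
    tube_length: float = 25.0       # Å
    tube_radius: float = 3.0        # Å
    slope_a: float = 2.0            # kcal/mol per Å
    intercept_b: float = -50.0      # kcal/mol
    noise_sigma: float = 1.0        # kcal/mol
    planted_centers: tuple[tuple[tuple[float, float, float], float], ...] = ()
    dissociated_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 0:
            raise ValueError("n_poses must be non-negative")
        if not 0.0 <= self.dissociated_fraction <= 1.0:
            raise ValueError("dissociated_fraction must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(spread < 0 for _, spread in self.planted_centers):
            raise ValueError("planted spreads must be non-negative")


@dataclass
class GroundTruth:
    """Per-pose generative truth, aligned one-to-one with the ensemble."""

    planted_center: list[int | None]   # index into planted centers, or None
    true_energy: np.ndarray            # a·d_D + b, before noise
    energy: np.ndarray                 # with noise; what the pool sees
    dissociated: np.ndarray            # bool
    d_D: np.ndarray                    # Å, as generated


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()


def _place(template: Structure, com: np.ndarray, rng: np.random.Generator,
           label: str, rotate: bool = True) -> Structure:
    R = _random_rotation(rng) if rotate else np.eye(3)
    return template.transformed(R, com, label=label)


def generate_funnel_pool(spec: FunnelSpec
                         ) -> tuple[PoseEnsemble, Structure, GroundTruth]:
    """Generate (ensemble, destination pose, ground truth) under ``spec``.

    Bound pose centers are drawn uniformly along the tube (or at the planted
    centers ± isotropic Gaussian spread when centers are given); a
    ``dissociated_fraction`` of poses is parked beyond the 30 Å dissociation
    boundary.  Bit-identical for equal specs (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    template = ligand_template()
    destination = _place(template, np.zeros(3), rng, label="destination",
                         rotate=False)
    dest_com = destination.center_of_mass()

    n = spec.n_poses
    n_diss = int(round(spec.dissociated_fraction * n))
    n_bound = n - n_diss
    is_diss = np.zeros(n, dtype=bool)
    if n_diss:
        is_diss[rng.choice(n, size=n_diss, replace=False)] = True

    poses, centers_idx, d_D = [], [], np.empty(n)
    for i in range(n):
        if is_diss[i]:
            r = rng.uniform(DISSOCIATED_MIN_DD, DISSOCIATED_MAX_DD)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            com = dest_com + r * direction
            centers_idx.append(None)
        elif spec.planted_centers:
            k = int(rng.integers(len(spec.planted_centers)))
            center, spread = spec.planted_centers[k]
            com = np.asarray(center, float) + rng.normal(scale=spread, size=3)
            centers_idx.append(k)
        else:
            x = rng.uniform(0.0, spec.tube_length)
            rad = spec.tube_radius * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2 * np.pi)
            com = dest_com + np.array([x, rad * np.cos(phi), rad * np.sin(phi)])
            centers_idx.append(None)
        pose = _place(template, com, rng, label=f"pose_{i:05d}")
        poses.append(pose)
        d_D[i] = np.linalg.norm(pose.center_of_mass() - dest_com)

    true_e = spec.slope_a * d_D + spec.intercept_b
    noise = rng.normal(scale=spec.noise_sigma, size=n) if spec.noise_sigma else 0.0
    truth = GroundTruth(
        planted_center=centers_idx,
        true_energy=true_e,
        energy=true_e + noise,
        dissociated=is_diss,
        d_D=d_D,
    )
    ensemble = PoseEnsemble(poses=poses, label=f"funnel_seed{spec.seed}")
    return ensemble, destination, truth


def funnel_conformation_pool(spec: FunnelSpec) -> tuple[ConformationPool, GroundTruth]:
    """Funnel pool assembled into a filtered :class:`ConformationPool`
    (dissociation filter applied; no contact trimming — no protein here)."""
    ensemble, destination, truth = generate_funnel_pool(spec)
    pool = build_pool(ensemble, destination, energies=truth.energy)
    return pool, truth


def generate_cluster_fixture(K: int, separation: float, spread: float,
                             n_per_cluster: int, seed: int = 0,
                             resolution: float = 1.75,
                             ) -> tuple[ConformationPool, np.ndarray]:
    """K planted pose blobs on a line, ``separation`` Å apart, with isotropic
    Gaussian COM spread.

    Offsets are truncated at min(2·spread, resolution/2) so each blob's
    support diameter stays below the clustering ``resolution`` (the d_rnk the
    fixture is meant to challenge) — beyond that diameter planted membership
    is not identifiable by any d_min rule, so recovery would be ill-posed.
    Poses within a fixture share one orientation; orientational diversity is
    exercised by the funnel generator.  Energies are drawn so blob minima are
    unique and ordered.  Returns the assembled pool and the ground-truth blob
    label per pose.
    """
    if K < 1 or n_per_cluster < 1:
        raise ValueError("K and n_per_cluster must be positive")
    if separation <= 2 * spread:
        raise ValueError("separation must exceed twice the spread")
    rng = np.random.default_rng(seed)
    template = ligand_template()
    destination = _place(template, np.zeros(3), rng, label="destination",
                         rotate=False)

    cap = min(2.0 * spread, resolution / 2.0)
    poses, labels, energies = [], [], []
    for k in range(K):
        center = np.array([5.0 + k * separation, 0.0, 0.0])
        for j in range(n_per_cluster):
            offset = rng.normal(scale=spread, size=3) if spread > 0 else np.zeros(3)
            norm = np.linalg.norm(offset)
            if cap > 0 and norm > cap:
                offset *= cap / norm
            pose = _place(template, center + offset, rng,
                          label=f"blob{k}_pose{j}", rotate=False)
            poses.append(pose)
            labels.append(k)
            energies.append(-60.0 + 1.5 * k + float(rng.uniform(0.0, 1.2)))
    ensemble = PoseEnsemble(poses=poses, label=f"clusters_K{K}_seed{seed}")
    pool = build_pool(ensemble, destination, energies=energies,
                      dissociation_cutoff=np.inf)
    return pool, np.asarray(labels)


def generate_step_trajectory(step_time: float, before: float, after: float,
                             n_frames: int, dt: float, jitter: float = 0.0,
                             seed: int = 0, label: str = "step") -> DistanceSeries:
    """Noisy step series: ``before`` Å for t < step_time, ``after`` Å from
    ``step_time`` on, plus N(0, jitter²), clipped at zero (distances)."""
    times = np.arange(n_frames, dtype=float) * dt
    if not times[0] <= step_time <= times[-1]:
        raise ValueError("step_time outside the trajectory span")
    values = np.where(times < step_time, before, after).astype(float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(scale=jitter, size=n_frames), 0.0, None)
    return DistanceSeries(label=label, times=times, values=values)
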