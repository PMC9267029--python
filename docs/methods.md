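# Methods

This note documents the models, rules, defaults and numerical choices
implemented in `netbinder`, what the synthetic generators do and do not
emulate, and the known limitations.

## Scope and data model

The pipeline operates on rigid ligand pose ensembles in the coordinate
frame of a (fixed) protein target. Poses are read from multi-model PDB
files or directories of per-frame PDBs (biotite does the parsing; both
ATOM and HETATM records are accepted, only the first alternate location
is kept, insertion codes are part of residue identity). Coordinates are
Å throughout; masses are standard atomic masses (IUPAC 2021 abridged)
built into the package — an element without a tabulated mass is a hard
error rather than a silent default. When a file carries no element
columns, elements are inferred from atom names with a residue-aware rule:
two-letter elements are only accepted when the residue itself is the
ion/metal entry (so " CA " in ALA is carbon, "CA" in residue CA is
calcium), and digit-led names ("1HB") resolve to hydrogen.

## Interaction energy

`E_inter` is the intermolecular 12-6 Lennard-Jones double sum over all
ligand×target atom pairs:

E_inter = Σ_ij ( A_ij/r_ij¹² − B_ij/r_ij⁶ ), A_ij = ε_ij R_ij¹²,
B_ij = 2 ε_ij R_ij⁶, with R_ij = R_i + R_j and ε_ij = √(ε_i ε_j).

Choices and caveats:

* **Parameters.** Per-atom R_i (Rmin/2, Å) and ε_i (kcal/mol) in the
  Amber convention, shipped as an element-keyed TSV
  (`src/netbinder/data/lj_params.tsv`). Ligand-specific atom typing is a
  user input: tables can be keyed by atom name or explicit
  residue:name addresses, and per-atom overrides take precedence.
  Unresolvable atoms are an error listing the offenders — never a
  default.
* **No cutoff by default.** The energy is the full double sum; a cutoff
  argument exists but is off. (An MD engine's nonbonded cutoff is a
  simulation concern, not part of this score.)
* **No electrostatics, no solvation.** This is a van-der-Waals score for
  ranking poses, not a total interaction or binding free energy.
* Hydrogens contribute iff they carry parameters; the shipped table
  includes H.
* A coincident pair (r = 0) is singular and raises.

The engine is vectorised (scipy `cdist` + outer combination rules); its
unit tests compare it against an independently coded brute-force double
loop at 1e-10 relative tolerance.

## Pooling and filters

Each pose is annotated with `E_inter` and `d_D`, the Euclidean distance
between the pose's center of mass and that of the reference destination
pose. Centers of mass are mass-weighted over **all** atoms present
(hydrogens included when present) — the literal reading of "center of
mass"; a `heavy_only` flag exists for sensitivity checks.

Two filters prune the pool; they commute, and the retained set is
monotone in both cutoffs:

* **Contact trimming** (default 3.5 Å, **inclusive** ≤): a pose is kept
  iff its minimum heavy-atom distance to any heavy atom of the declared
  binding-cavity residues is within the cutoff. Heavy atoms only, on
  both sides, consistent with the heavy-atom convention of the
  clustering distance; "maximum distance" reads as inclusive.
* **Dissociation** (default 30 Å, **strict** >): a pose whose d_D
  exceeds the cutoff has left the cavity. d_D = 30.0 Å exactly is
  retained.

A pose failing both filters is labelled `dissociated`: leaving the cavity
is the stronger statement than merely losing contact. Identical poses are
never deduplicated. Poses are assumed to be expressed in the target's
frame (the sampling protocols this consumes restrain the protein
backbone); no superposition is applied.

## Greedy energy-ranked clustering

Retained entries are visited by ascending E_inter (ties broken by
ascending pose index — stable and input-order independent). The first
entry founds cluster 1 and is its representative (PM_1). Each subsequent
entry founds a new cluster iff its closest heavy-atom distance d_min to
**every** existing representative exceeds the ranking tolerance
d_rnk = 1.75 Å; otherwise it joins the nearest representative within
tolerance (the deterministic generalisation of the two-cluster rule).
d_min is measured against representatives only, not against all current
members. Output invariants, asserted in tests: representatives are
pairwise separated by more than d_rnk; every member lies within d_rnk of
its own representative; PM_1 attains the pool's minimum energy; the
result is invariant under permutation of the input.

PMs are numbered by ascending representative energy. A distance-sorted
view of the PM table is available for presentation but never renumbers.

## Energy slope

Ordinary least squares of E_inter on d_D (scipy `linregress`); r² is the
squared Pearson correlation. Degenerate inputs: fewer than two points or
zero variance in d_D raise; a constant-energy input returns the
perfect-fit limit (slope 0, r² = 1) since the horizontal line fits
exactly and Pearson r is undefined there.

## Binding network

Nodes are PMs (attributes: d_D, E_inter, degree, hub and backbone
flags); edge lengths are center-of-mass distances d_PM.

* **Edge rule.** Candidate edges are pairs with d_PM ≤ 12 Å, boundary
  inclusive — roughly one ligand length, so an edge is a single-step
  move. Pairs farther apart are never connected.
* **Degree cap** (default 10). Each node ranks its candidates by length
  and keeps its 10 nearest; an edge survives if **either** endpoint
  keeps it. If that union leaves a node over the cap, the highest-degree
  node (ties: lowest id) repeatedly sheds its longest surviving edge
  until all degrees comply. Fully deterministic; with the cap disabled
  the graph equals the pure cutoff graph (asserted against a brute-force
  oracle).
* **Exclusion.** Nodes with no surviving edge are dropped from the graph
  and reported separately.
* **Hubs and backbone.** Hubs are nodes with degree strictly greater
  than 4. The backbone is the largest connected component of the
  hub-induced subgraph (ties: the component containing the lowest node
  id). The backbone is connected by construction and a subset of the
  hubs.
* **Destination node.** The destination pose is not a node by default;
  `destination_mode()` creates a pm_id-0 pseudo-node at d_D = 0 to
  include it, since published node counts may follow either convention.
* **Pathway.** Dijkstra shortest path (networkx) by total d_PM from the
  node of maximal d_D (cavity entrance) to the node of minimal d_D
  (nearest the destination), endpoints overridable. Disconnected
  endpoints raise a no-path error.

Graphs export as edge-list TSV, node-attribute TSV and GraphML.

## Trajectory events

Distance series are extracted per frame, either between two uniquely
selected atoms (`chain:resid:atom` or `resname:atom` selectors) or as
d_D against a fixed reference pose. Frame times come from input
metadata; without them, unit-spaced indices are used and reported as
frames, not ns.

The event-start rule is **sustained stability**: the final value is the
mean over the trailing terminal window (default 100 ns); the start time
is the earliest time after which the trace never again leaves
±tolerance (default 1.0 Å) of that mean. A transient dip into the band
does not count — the last sustained entry wins. If even the final frame
lies outside the band around the terminal mean, the last frame is
reported (the trace never stabilised). The rule is equivariant under
time shifts, and tightening the tolerance can only delay the start.
Published event times are typically read off by inspection; this rule is
an explicit, testable operationalisation of the same idea. Angle-based
events (ligand flips) are proxied by distance selectors only; dihedral
series are out of scope.

## Synthetic generators

All generators are pure functions of their spec (seed included) and
round-trip through the PDB I/O. The shared ligand is a hand-written
rigid fragment: a phenol-like six-ring with a hydroxyl oxygen (`OH`,
with hydrogen) and an acetyl arm with a carbonyl oxygen (`O1`) — 10
heavy atoms plus 3 hydrogens, so Table-style selectors (`LIG:OH`) are
exercisable. Generated energies are attached to poses directly,
bypassing the LJ engine, which keeps clustering/slope tests independent
of the energy engine's own tests.

* **Funnel pool** (defaults: 500 poses, tube 25 Å × 3 Å radius, slope
  2 kcal/mol/Å, intercept −50 kcal/mol, noise σ = 1 kcal/mol). Pose
  centers are uniform in the tube (or Gaussian around planted centers);
  orientations are uniformly random rotations; each pose's energy is
  a·d_D + b + N(0, σ²) with d_D measured from the actually placed pose.
  A `dissociated_fraction` of poses is parked isotropically at
  d_D ∈ [32, 45] Å, beyond the 30 Å rule.
* **Cluster fixture.** K blobs on a line, `separation` apart (must
  exceed 2·spread), isotropic Gaussian COM offsets truncated at
  min(2·spread, resolution/2) so each blob's support diameter stays
  below the clustering resolution d_rnk — beyond that diameter planted
  membership is not identifiable by any d_min rule, so "recovery" would
  be ill-posed. Poses within a fixture share one orientation
  (orientational diversity is exercised by the funnel generator); blob
  energy ranges are disjoint so blob minima are unique. Under these
  conditions recovery of the planted partition is exact by
  construction, which is what the recovery tests assert across seeds.
* **Step trajectory.** A before/after step at a known time with optional
  Gaussian jitter, clipped at zero.

What the generators do **not** emulate: protein flexibility, explicit
water, realistic pose geometry inside a protein (the "cavity" is a bare
tube with no protein atoms, so contact trimming is exercised only on
hand-built fixtures), correlated noise along a trajectory, and any
relationship between pose orientation and energy. Passing recovery
tests therefore demonstrate the correctness of the algorithms under the
stated generative model, not the physics of a real binding funnel.

## Problem sizes

Default test and acceptance runs use pools of ≤ 500 poses, 20 replicate
fixtures per recovery property, 100–200 random instances per oracle
comparison, and 10 000-frame step trajectories. These sizes give stable
statistics (slope standard errors ≈ 0.007 kcal/mol/Å at n = 500) while
keeping the whole suite in a few seconds.

## Known limitations

* The LJ score ignores electrostatics; rankings for strongly polar or
  charged ligands will differ from force-field interaction energies.
* Clustering is the greedy energy-ranked rule only — intentionally; no
  RMSD or hierarchical alternatives are offered.
* Pose ensembles must share atom ordering; no topology matching is
  attempted.
* The degree-cap pruning order (longest-edge-first from the
  highest-degree node) is one deterministic choice among several
  reasonable ones; published graphs built with other tie-breaks may
  differ in a few edges when the cap binds.
* mmCIF and binary trajectory formats are not read; convert to PDB
  first.
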