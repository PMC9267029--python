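"""Pool assembly: d_D annotation, contact trimming, dissociation filter."""

import numpy as np
import pytest

from netbinder.pooling import (
    build_pool,
    compute_dD,
    filter_dissociated,
    parse_cavity_residues,
    trim_by_contact,
)
from netbinder.structures import PoseEnsemble

from conftest import make_atom, make_structure


def ligand_at(shift, label="pose"):
    base = [("C1", "C", (0.0, 0.0, 0.0)), ("O1", "O", (1.2, 0.0, 0.0)),
            ("H1", "H", (-0.6, 0.8, 0.0))]
    s = np.asarray(shift, dtype=float)
    return make_structure([(n, e, tuple(np.add(c, s))) for n, e, c in base],
                          label=label)


@pytest.fixture
def mini_target():
    return make_structure(
        [
            make_atom(1, "CA", "C", (10.0, 0.0, 0.0), "ALA", 238, "A"),
            make_atom(2, "CB", "C", (10.0, 2.0, 0.0), "ALA", 238, "A"),
            make_atom(3, "HB1", "H", (9.2, 2.5, 0.0), "ALA", 238, "A"),
            make_atom(4, "CA", "C", (20.0, 0.0, 0.0), "GLY", 300, "A"),
        ],
        label="target",
    )


class TestComputeDD:
    def test_identical_poses_zero(self):
        pose = ligand_at((0, 0, 0))
        assert compute_dD(pose, pose) == 0.0

    def test_pure_translation(self):
        assert compute_dD(ligand_at((0, 0, 0)), ligand_at((3, 4, 0))) == \
            pytest.approx(5.0)

    def test_hand_computed_two_atom_poses(self):
        # COM_a = (15.999*2/28.010, 0, 0); COM_b at x+10 for the same molecule
        a = make_structure([("C1", "C", (0, 0, 0)), ("O1", "O", (2, 0, 0))])
        b = make_structure([("C1", "C", (10, 0, 0)), ("O1", "O", (12, 0, 0))])
        assert compute_dD(a, b) == pytest.approx(10.0, abs=1e-9)

    def test_heavy_only_option_changes_weighting(self):
        # hydrogen placed asymmetrically: all-atom and heavy-only COMs differ
        a = ligand_at((0, 0, 0))
        b = ligand_at((0, 0, 0))
        assert compute_dD(a, b, heavy_only=True) == 0.0
        assert a.center_of_mass() != pytest.approx(
            a.center_of_mass(heavy_only=True))


class TestTrimByContact:
    def test_contact_retained_far_trimmed_boundary_inclusive(self, mini_target):
        # nearest heavy-atom contact 2.0, 5.0 and exactly 3.5 Å:
        # CB of A:238 sits at (10, 2, 0); pose C1 is the nearest heavy atom
        ens = PoseEnsemble(poses=[
            ligand_at((10.0, 4.0, 0.0)),   # C1 2.0 Å from CB -> retained
            ligand_at((10.0, 7.0, 0.0)),   # 5.0 Å -> trimmed
            ligand_at((10.0, 5.5, 0.0)),   # exactly 3.5 Å -> retained
        ])
        flags = trim_by_contact(ens, mini_target, "A:238", cutoff=3.5)
        assert flags.tolist() == [True, False, True]

    def test_hydrogens_ignored_on_both_sides(self, mini_target):
        # H1 of the pose is 1.0 Å below HB1 of the target, but the closest
        # heavy-heavy pair is far: the pose must be trimmed
        pose = ligand_at((9.8, 1.7, 1.0))
        pose_h = pose.atoms[2]
        hb1 = mini_target.atoms[2]
        assert np.linalg.norm(
            np.subtract(pose_h.coords, hb1.coords)) < 3.5  # H contact exists
        ens = PoseEnsemble(poses=[pose])
        flags = trim_by_contact(ens, mini_target, "A:300", cutoff=3.5)
        assert flags.tolist() == [False]

    def test_brute_force_min_distance_oracle(self, mini_target, rng):
        cavity = parse_cavity_residues("A:238")
        heavy_target = [a for a in mini_target.atoms
                        if a.residue_id == 238 and a.is_heavy]
        for _ in range(20):
            pose = ligand_at(rng.uniform(5, 15, 3))
            want = min(
                np.linalg.norm(np.subtract(pa.coords, ta.coords))
                for pa in pose.atoms if pa.is_heavy
                for ta in heavy_target
            ) <= 3.5
            got = trim_by_contact(PoseEnsemble(poses=[pose]), mini_target,
                                  "A:238")[0]
            assert got == want

    def test_unresolvable_residue(self, mini_target):
        with pytest.raises(ValueError, match="not found"):
            trim_by_contact(PoseEnsemble(poses=[ligand_at((0, 0, 0))]),
                            mini_target, "B:999")


class TestFilterDissociated:
    def test_strict_boundary(self):
        flags = filter_dissociated([31.0, 30.0, 29.9, 0.0])
        assert flags.tolist() == [False, True, True, True]

    def test_empty(self):
        assert filter_dissociated([]).tolist() == []


class TestBuildPool:
    def test_composition_of_filters(self, mini_target):
        dest = ligand_at((10.0, 4.0, 0.0), label="destination")
        ens = PoseEnsemble(poses=[
            ligand_at((10.0, 4.0, 0.0)),    # in contact, d_D = 0 -> retained
            ligand_at((10.0, 8.0, 0.0)),    # no contact -> trimmed
            ligand_at((50.0, 4.0, 0.0)),    # d_D = 40 -> dissociated
        ])
        pool = build_pool(ens, dest, target=mini_target,
                          cavity_residues="A:238",
                          energies=[-50.0, -40.0, -5.0])
        assert pool.counts == {"input": 3, "trimmed": 1, "dissociated": 1,
                               "retained": 1}
        reasons = [e.rejection_reason for e in pool.entries]
        assert reasons == ["none", "trimmed", "dissociated"]
        df = pool.to_dataframe()
        assert df.loc[0, "d_D_A"] == pytest.approx(0.0)
        assert df.loc[2, "d_D_A"] == pytest.approx(40.0)

    def test_empty_ensemble(self):
        dest = ligand_at((0, 0, 0), label="destination")
        pool = build_pool(PoseEnsemble(poses=[]), dest, energies=[])
        assert pool.counts == {"input": 0, "trimmed": 0, "dissociated": 0,
                               "retained": 0}

    def test_deterministic(self, mini_target):
        dest = ligand_at((10.0, 4.0, 0.0))
        ens = PoseEnsemble(poses=[ligand_at((10.0, 4.0, 0.0)),
                                  ligand_at((12.0, 4.0, 0.0))])
        kw = dict(target=mini_target, cavity_residues="A:238",
                  energies=[-1.0, -2.0])
        df1 = build_pool(ens, dest, **kw).to_dataframe()
        df2 = build_pool(ens, dest, **kw).to_dataframe()
        assert df1.equals(df2)

    def test_filter_order_independence(self, mini_target, rng):
        """Trim-then-dissociate equals dissociate-then-trim: the retained
        set is the intersection of the two per-filter retained sets."""
        dest = ligand_at((10.0, 4.0, 0.0))
        poses = [ligand_at(rng.uniform(0, 60, 3)) for _ in range(30)]
        ens = PoseEnsemble(poses=poses)
        pool = build_pool(ens, dest, target=mini_target,
                          cavity_residues="A:238",
                          energies=np.zeros(30))
        contact = trim_by_contact(ens, mini_target, "A:238")
        assoc = filter_dissociated([compute_dD(p, dest) for p in poses])
        want = contact & assoc
        got = np.array([e.retained for e in pool.entries])
        assert (got == want).all()

    def test_retained_set_monotone_in_cutoffs(self, mini_target, rng):
        dest = ligand_at((10.0, 4.0, 0.0))
        poses = [ligand_at(rng.uniform(0, 50, 3)) for _ in range(25)]
        ens = PoseEnsemble(poses=poses)

        def retained(contact_cut, dissoc_cut):
            pool = build_pool(ens, dest, target=mini_target,
                              cavity_residues="A:238", energies=np.zeros(25),
                              contact_cutoff=contact_cut,
                              dissociation_cutoff=dissoc_cut)
            return {e.pose_index for e in pool.retained_entries()}

        base = retained(3.5, 30.0)
        assert base <= retained(8.0, 30.0)
        assert base <= retained(3.5, 45.0)
        assert base <= retained(8.0, 45.0)
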