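"""Principal axes, head angles, H-bond/salt-bridge counts, RMSD."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import poremorph as pm
from poremorph.metrics import Chemistry, head_angles, principal_axes


def brute_force_hbonds(donors, donor_h, acceptors, r_max=0.35,
                       angle_max=30.0):
    """All-pairs hydrogen-bond oracle."""
    count = 0
    for d, h in zip(donors, donor_h):
        for a in acceptors:
            if np.linalg.norm(a - d) > r_max:
                continue
            u, v = h - d, a - d
            cos = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            if math.degrees(math.acos(np.clip(cos, -1, 1))) <= angle_max:
                count += 1
    return count


def brute_force_saltbridges(pos_ids, pos_xyz, neg_ids, neg_xyz, r_max=0.40):
    pairs = set()
    for i, p in zip(pos_ids, pos_xyz):
        for j, q in zip(neg_ids, neg_xyz):
            if np.linalg.norm(p - q) <= r_max:
                pairs.add((int(i), int(j)))
    return len(pairs)


def strand_chemistry(n_bonds, offset_y, pull=0.0):
    """Two facing ideal antiparallel strand fragments, built to bond.

    Region A donates along +y toward region B's carbonyl oxygens at
    N...O = 0.29 nm (stretched by ``pull``), collinear N-H...O.
    """
    z = np.arange(n_bonds) * 0.35
    donors = np.column_stack([np.zeros(n_bonds), np.zeros(n_bonds), z])
    hydrogens = donors + [0.0, 0.1, 0.0]
    acceptors = donors + [0.0, 0.29 + pull + offset_y, 0.0]
    empty = np.empty((0, 3))
    region_a = Chemistry(donors=donors, donor_h=hydrogens, acceptors=empty,
                         positive_ids=np.array([]), positive_xyz=empty,
                         negative_ids=np.array([]), negative_xyz=empty)
    region_b = Chemistry(donors=empty, donor_h=None, acceptors=acceptors,
                         positive_ids=np.array([]), positive_xyz=empty,
                         negative_ids=np.array([]), negative_xyz=empty)
    return region_a, region_b


class TestPrincipalAxes:
    def test_line_segment_along_z(self):
        pts = np.column_stack([0.01 * (np.arange(10) % 2),
                               np.linspace(0, 0.1, 10),
                               np.linspace(0, 5, 10)])
        axes = principal_axes(pts)
        assert abs(axes[0] @ [0, 0, 1]) > 0.999

    def test_axis_aligned_ellipsoid(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, (4000, 3)) * [3.0, 1.0, 2.0]
        axes = principal_axes(pts)
        assert abs(axes[0] @ [1, 0, 0]) > 0.99
        assert abs(axes[1] @ [0, 0, 1]) > 0.99
        assert abs(axes[2] @ [0, 1, 0]) > 0.99

    def test_rotation_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (500, 3)) * [3.0, 1.0, 2.0]
        base = principal_axes(pts, ref1=(1, 1, 1), ref2=(1, -1, 0))
        rot = Rotation.from_euler("xyz", [12, -7, 33], degrees=True)
        rotated = principal_axes(rot.apply(pts),
                                 ref1=rot.apply([1, 1, 1]),
                                 ref2=rot.apply([1, -1, 0]))
        for k in range(3):
            assert np.abs(rotated[k] - rot.apply(base[k])).max() < 1e-9

    def test_degenerate_sphere_rejected(self):
        octahedron = np.vstack([np.eye(3), -np.eye(3)])
        with pytest.raises(ValueError, match="degenerate"):
            principal_axes(octahedron)  # exactly isotropic second moments

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            principal_axes(np.zeros((2, 3)))


class TestHeadAngles:
    def test_reference_pose(self, monomer, partition):
        ang = head_angles(monomer.coords, monomer.res_ids, partition,
                          radial_ref=(1, 0, 0))
        assert ang.tau == pytest.approx(0.0, abs=1e-3)
        assert ang.chi == pytest.approx(90.0, abs=1e-3)
        assert ang.alpha == pytest.approx(0.0, abs=1e-3)
        assert abs(ang.ph1 @ ang.ph2) < 1e-6
        assert abs(ang.pb1 @ ang.pb3) < 1e-6

    @pytest.mark.parametrize("tilt", [5.0, 15.0, 25.0])
    def test_tau_recovers_constructed_tilt(self, partition, tilt):
        m = pm.make_monomer_fixture(
            geometry=pm.MonomerGeometry(head_tilt_deg=tilt), rng_seed=1)
        ang = head_angles(m.coords, m.res_ids, partition, radial_ref=(1, 0, 0))
        assert ang.tau == pytest.approx(tilt, abs=0.5)

    @pytest.mark.parametrize("roll", [-40.0, 25.0, 60.0])
    def test_alpha_recovers_constructed_roll(self, partition, roll):
        m = pm.make_monomer_fixture(
            geometry=pm.MonomerGeometry(head_roll_deg=roll), rng_seed=1)
        ang = head_angles(m.coords, m.res_ids, partition, radial_ref=(1, 0, 0))
        assert ang.alpha == pytest.approx(roll, abs=0.5)

    def test_alpha_additive_under_composed_rolls(self, monomer, partition):
        # Rotating the measured pose further about PB1 adds to alpha.
        from poremorph.synthetic import _rotation
        for a1, a2 in [(20.0, 30.0), (-30.0, 15.0), (35.0, 40.0)]:
            m1 = pm.make_monomer_fixture(
                geometry=pm.MonomerGeometry(head_roll_deg=a1), rng_seed=1)
            head_mask = m1.domain_atom_mask("head")
            coords = m1.coords.copy()
            centre = coords[head_mask].mean(axis=0) * [1, 1, 0]
            coords[head_mask] = (coords[head_mask] - centre) \
                @ _rotation("z", a2).T + centre
            ang = head_angles(coords, m1.res_ids, partition,
                              radial_ref=(1, 0, 0))
            expected = (a1 + a2 + 180) % 360 - 180
            assert ang.alpha == pytest.approx(expected, abs=0.5)

    def test_rigid_motion_invariance(self, monomer, partition):
        base = head_angles(monomer.coords, monomer.res_ids, partition,
                           radial_ref=(1, 0, 0))
        rot = Rotation.from_euler("zyx", [33, 12, -41], degrees=True)
        moved = rot.apply(monomer.coords) + [3.0, -1.0, 2.0]
        ang = head_angles(moved, monomer.res_ids, partition,
                          radial_ref=rot.apply([1, 0, 0]))
        assert ang.tau == pytest.approx(base.tau, abs=1e-4)
        assert ang.chi == pytest.approx(base.chi, abs=1e-4)
        assert ang.alpha == pytest.approx(base.alpha, abs=1e-4)


class TestHydrogenBonds:
    def test_constructed_strand_bonds_counted(self):
        a, b = strand_chemistry(4, 0.0)
        assert pm.count_hydrogen_bonds(a, b) == 4

    def test_stretched_beyond_cutoff_zero(self):
        a, b = strand_chemistry(4, 0.0, pull=0.21)   # N...O = 0.50 nm
        assert pm.count_hydrogen_bonds(a, b) == 0

    @pytest.mark.parametrize("h_dir,expected_per_bond", [
        ((0.0, 0.1, 0.0), 1),       # collinear with D->A
        ((0.04, 0.09, 0.0), 1),     # 24 deg off: within the 30 deg cone
        ((0.08, -0.06, 0.0), 0),    # 127 deg off: rejected
    ])
    def test_angle_criterion(self, h_dir, expected_per_bond):
        a, b = strand_chemistry(3, 0.0)
        a.donor_h = a.donors + list(h_dir)
        assert pm.count_hydrogen_bonds(a, b) == 3 * expected_per_bond

    def test_matches_brute_force_oracle_random(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            donors = rng.uniform(0, 2.0, (40, 3))
            hydrogens = donors + rng.normal(0, 0.07, (40, 3))
            acceptors = rng.uniform(0, 2.0, (50, 3))
            empty = np.empty((0, 3))
            a = Chemistry(donors=donors, donor_h=hydrogens, acceptors=empty,
                          positive_ids=np.array([]), positive_xyz=empty,
                          negative_ids=np.array([]), negative_xyz=empty)
            b = Chemistry(donors=empty, donor_h=None, acceptors=acceptors,
                          positive_ids=np.array([]), positive_xyz=empty,
                          negative_ids=np.array([]), negative_xyz=empty)
            assert pm.count_hydrogen_bonds(a, b) == brute_force_hbonds(
                donors, hydrogens, acceptors)

    def test_empty_region_warns_and_returns_zero(self):
        empty = np.empty((0, 3))
        bare = Chemistry(donors=empty, donor_h=None, acceptors=empty,
                         positive_ids=np.array([]), positive_xyz=empty,
                         negative_ids=np.array([]), negative_xyz=empty)
        with pytest.warns(UserWarning):
            assert pm.count_hydrogen_bonds(bare, bare) == 0


class TestSaltBridges:
    def _chem(self, ids, xyz, positive):
        empty = np.empty((0, 3))
        kw = dict(donors=empty, donor_h=None, acceptors=empty,
                  positive_ids=np.array([]), positive_xyz=empty,
                  negative_ids=np.array([]), negative_xyz=empty)
        if positive:
            kw["positive_ids"] = np.asarray(ids)
            kw["positive_xyz"] = np.asarray(xyz, dtype=float)
        else:
            kw["negative_ids"] = np.asarray(ids)
            kw["negative_xyz"] = np.asarray(xyz, dtype=float)
        return Chemistry(**kw)

    def test_within_cutoff_counts_once_per_residue_pair(self):
        pos = self._chem([1, 1], [[0, 0, 0], [0.05, 0, 0]], True)
        neg = self._chem([9], [[0.35, 0, 0]], False)
        assert pm.count_salt_bridges(pos, neg) == 1

    def test_beyond_cutoff_zero(self):
        pos = self._chem([1], [[0, 0, 0]], True)
        neg = self._chem([9], [[0.45, 0, 0]], False)
        assert pm.count_salt_bridges(pos, neg) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        pos_xyz = rng.uniform(0, 1.5, (25, 3))
        neg_xyz = rng.uniform(0, 1.5, (25, 3))
        pos_ids = rng.integers(0, 10, 25)
        neg_ids = rng.integers(100, 110, 25)
        pos = self._chem(pos_ids, pos_xyz, True)
        neg = self._chem(neg_ids, neg_xyz, False)
        assert pm.count_salt_bridges(pos, neg) == brute_force_saltbridges(
            pos_ids, pos_xyz, neg_ids, neg_xyz)


class TestNeighborInteractionReport:
    def test_linear_fixture_exact_counts(self, monomer, partition):
        # By construction each adjacent pair at the design spacing forms one
        # hairpin bond per strand residue, one head bond and one bridge.
        n_per_pair = len(monomer.domain_map["hairpin"]) // 2
        lin = pm.build_linear(monomer, 4, monomer.geometry.neighbor_spacing)
        rep = pm.neighbor_interaction_report(lin, partition)
        hb = rep.per_frame.set_index("subunit")["HB_beta"]
        assert hb[0] == hb[3] == n_per_pair           # terminals: 1 neighbour
        assert hb[1] == hb[2] == 2 * n_per_pair       # interior: 2 neighbours
        assert list(rep.per_frame["SB_head"]) == [1, 2, 2, 1]

    def test_ring_counts_uniform_and_cyclic(self, monomer, partition):
        spacing = monomer.geometry.neighbor_spacing
        n = 60
        ring = pm.build_ring(monomer, n, spacing / (2 * math.sin(math.pi / n)))
        rep = pm.neighbor_interaction_report(ring, partition)
        counts = rep.per_frame[["HB_beta", "HB_head", "SB_head"]]
        assert (counts.nunique() == 1).all()          # cyclic: all equal
        assert counts["HB_beta"].iloc[0] \
            == 2 * (len(monomer.domain_map["hairpin"]) // 2)

    def test_separated_subunits_all_zero(self, monomer, partition):
        lin = pm.build_linear(monomer, 3, 10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pm.neighbor_interaction_report(lin, partition)
        assert (rep.per_frame[["HB_beta", "HB_head", "SB_head"]] == 0) \
            .all().all()

    def test_summary_has_boxplot_statistics(self, monomer, partition):
        lin = pm.build_linear(monomer, 4, monomer.geometry.neighbor_spacing)
        rep = pm.neighbor_interaction_report([lin, lin], partition)
        assert set(rep.summary.columns) == {"metric", "q1", "median", "q3",
                                            "mean"}
        assert len(rep.per_frame) == 8                # 2 frames x 4 subunits

    def test_rigid_motion_invariance_of_counts(self, monomer, partition):
        lin = pm.build_linear(monomer, 3, monomer.geometry.neighbor_spacing)
        rep1 = pm.neighbor_interaction_report(lin, partition)
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        moved = pm.OligomerModel(
            [rot.apply(s) + [1.0, 2.0, -0.5] for s in lin.subunits],
            monomer, "linear", spacing=lin.spacing)
        rep2 = pm.neighbor_interaction_report(moved, partition)
        cols = ["HB_beta", "HB_head", "SB_head"]
        assert rep1.per_frame[cols].equals(rep2.per_frame[cols])


class TestRmsdCa:
    def test_identity_zero(self, monomer):
        ca = monomer.coords[monomer.atom_names == "CA"]
        assert pm.rmsd_ca(ca, ca) == pytest.approx(0.0, abs=1e-12)

    def test_translation_closed_form(self, monomer):
        ca = monomer.coords[monomer.atom_names == "CA"]
        assert pm.rmsd_ca(ca + [1, 0, 0], ca, fit=True) \
            == pytest.approx(0.0, abs=1e-9)
        assert pm.rmsd_ca(ca + [1, 0, 0], ca, fit=False) \
            == pytest.approx(1.0, abs=1e-12)

    def test_noise_expectation(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 5, (100, 3))
        noisy = Rotation.random(rng=rng).apply(ref) \
            + rng.normal(0, 0.05, ref.shape)
        assert pm.rmsd_ca(noisy, ref, fit=True) \
            == pytest.approx(0.05 * math.sqrt(3), rel=0.05)

    def test_fit_never_exceeds_unfit(self, monomer):
        rng = np.random.default_rng(4)
        ca = monomer.coords[monomer.atom_names == "CA"]
        for _ in range(5):
            frame = Rotation.random(rng=rng).apply(ca) \
                + rng.normal(0, 0.2, ca.shape)
            assert pm.rmsd_ca(frame, ca, fit=True) \
                <= pm.rmsd_ca(frame, ca, fit=False) + 1e-12

    def test_shape_mismatch_rejected(self, monomer):
        ca = monomer.coords[monomer.atom_names == "CA"]
        with pytest.raises(ValueError):
            pm.rmsd_ca(ca[:-1], ca)
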