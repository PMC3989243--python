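"""H-bond detection, contacts, stacking and pairwise energies."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligodestab import interactions, synth
from oligodestab.model import AtomRecord, Frame, Topology, Trajectory

from conftest import brute_force_hbonds, make_hbond_fixture


def triple_topology(dha_angle_deg, n_o_dist):
    """One N-H donor and one O acceptor with exact D-H-A angle and D...A
    distance: the acceptor is placed from the hydrogen at the requested
    angle, with its range solved so the donor-acceptor distance comes out
    exactly as asked."""
    h = np.array([0.0, 0.0, 1.0])  # N at origin, N-H along z
    theta = np.radians(dha_angle_deg)
    u = np.array([np.sin(np.pi - theta), 0.0, np.cos(np.pi - theta)])
    # |H + t*u| = d with u.H = -cos(theta)
    t = np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1.0 + n_o_dist ** 2)
    o = h + t * u
    atoms = [
        AtomRecord(serial=1, name="N", element="N", chain_id="A",
                   residue_index=1, residue_name="GLY"),
        AtomRecord(serial=2, name="H", element="H", chain_id="A",
                   residue_index=1, residue_name="GLY"),
        AtomRecord(serial=3, name="O", element="O", chain_id="A",
                   residue_index=2, residue_name="GLY"),
    ]
    top = Topology(atoms, {1: 0})
    coords = np.array([[0.0, 0.0, 0.0], h, o])
    return top, Frame(coords)


class TestHBondCriterion:
    def test_good_geometry_detected(self):
        top, frame = triple_topology(165.0, 2.9)
        bonds = interactions.detect_hbonds(frame, top)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle == pytest.approx(165.0, abs=1e-6)

    def test_distance_boundary_strict(self):
        top, frame = triple_topology(179.0, 3.6)
        assert interactions.detect_hbonds(frame, top) == []
        top, frame = triple_topology(179.0, 3.5 + 1e-6)
        assert interactions.detect_hbonds(frame, top) == []
        top, frame = triple_topology(179.0, 3.5 - 1e-6)
        assert len(interactions.detect_hbonds(frame, top)) == 1

    def test_angle_boundary_strict(self):
        top, frame = triple_topology(150.0 - 1e-4, 3.0)
        assert interactions.detect_hbonds(frame, top) == []
        top, frame = triple_topology(150.0 + 1e-4, 3.0)
        assert len(interactions.detect_hbonds(frame, top)) == 1

    def test_refuses_hydrogen_free_topology(self):
        atoms = [AtomRecord(serial=1, name="O", element="O", chain_id="A",
                            residue_index=1, residue_name="GLY")]
        with pytest.raises(ValueError, match="no hydrogens"):
            interactions.detect_hbonds(Frame(np.zeros((1, 3))),
                                       Topology(atoms))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        top, frame = make_hbond_fixture(60, seed)
        fast = {(b.donor, b.hydrogen, b.acceptor)
                for b in interactions.detect_hbonds(frame, top)}
        assert fast == brute_force_hbonds(frame, top)


class TestBackboneSeries:
    def test_single_chain_has_no_interpeptide_bonds(self):
        from conftest import make_synthetic_helix
        top, frame = make_synthetic_helix(10)
        traj = Trajectory(top, [frame])
        assert interactions.backbone_hbond_count_series(traj)[0] == 0

    def test_ordered_pentamer_count(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 2)
        counts = interactions.backbone_hbond_count_series(traj)
        expected = synth.expected_interchain_hbonds(ordered_pentamer.spec)
        assert list(counts) == [expected, expected]


class TestHBondMap:
    def test_ordered_pair_is_diagonal(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 3)
        m = interactions.hbond_map(traj, ("A", "B"))
        assert not m.all_zero
        assert m.matrix.max() == 1.0
        diag = np.diag(m.raw_counts)
        off = m.raw_counts - np.diag(diag)
        assert diag.sum() > 0
        assert off.sum() == 0  # in-register ladder: strictly diagonal

    def test_c_terminal_breakage_visible(self, ordered_pentamer):
        """Breaking only C-terminal strand donors empties those map cells."""
        base = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 4)
        spec = ordered_pentamer.spec
        coords = []
        top = ordered_pentamer.topology
        for f in base.frames:
            c = f.coordinates.copy()
            for ci in range(1, spec.n_chains):
                chain = chr(ord("A") + ci)
                for r in range(spec.strand2[0], spec.strand2[1] + 1):
                    mask = ((top.chain_ids == chain)
                            & (top.residue_indices == r)
                            & np.isin(top.names, ["N", "H"]))
                    c[np.flatnonzero(mask)] += np.array([0.0, 2.5, 0.0])
            coords.append(Frame(c, f.time))
        broken = Trajectory(top, coords)
        m = interactions.hbond_map(broken, ("A", "B"))
        n_strand1 = spec.strand1[1] - spec.strand1[0] + 1
        assert m.raw_counts[:n_strand1].sum() > 0
        assert m.raw_counts[spec.strand2[0] - 1:].sum() == 0

    def test_same_chain_rejected(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 1)
        with pytest.raises(ValueError, match="distinct"):
            interactions.hbond_map(traj, ("A", "A"))

    def test_all_zero_map_flagged(self, ordered_pentamer):
        traj = synth.generate_trajectory(
            ordered_pentamer,
            synth.DisorderSpec(ladder_break_fraction=1.0, seed=1), 2)
        m = interactions.hbond_map(traj, ("A", "B"))
        assert m.all_zero
        assert m.matrix.sum() == 0


class TestContacts:
    def build_probe(self, distance):
        atoms = [
            AtomRecord(serial=1, name="CA", element="C", chain_id="A",
                       residue_index=1, residue_name="ALA"),
            AtomRecord(serial=2, name="CB", element="C", chain_id="A",
                       residue_index=1, residue_name="ALA"),
            AtomRecord(serial=3, name="C1", element="C", chain_id="X",
                       residue_index=2, residue_name="EGC", is_ligand=True,
                       molecule_id=1),
        ]
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5 + distance, 0, 0]])
        return Topology(atoms), Frame(coords)

    def test_sidechain_contact_at_3p4(self):
        top, frame = self.build_probe(3.4)
        contacts = interactions.ligand_contacts(frame, top, 1)
        assert ("A", 1, "sidechain") in contacts

    def test_no_contact_at_3p6(self):
        top, frame = self.build_probe(3.6)
        assert interactions.ligand_contacts(frame, top, 1) == set()

    def test_unknown_ligand_id(self, ordered_pentamer):
        with pytest.raises(ValueError, match="molecule_id 9"):
            interactions.ligand_contacts(ordered_pentamer.frame,
                                         ordered_pentamer.topology, 9)

    def test_profile_matches_per_frame_aggregation(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(seed=3), 6)
        traj = synth.place_ligands(
            traj, synth.LigandPlacement(site=[("B", 26)], n_copies=1), seed=4)
        profile = interactions.contact_profile(traj, [1])
        top = traj.topology
        for i, key in enumerate(profile.residues):
            hits = sum(1 for f in traj.frames
                       if (key[0], key[1], "sidechain")
                       in interactions.ligand_contacts(f, top, 1))
            assert profile.sidechain_probability[i] == pytest.approx(hits / 6)

    def test_never_contacting_ligand_is_all_zero(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 3)
        traj = synth.place_ligands(
            traj, synth.LigandPlacement(site=None, n_copies=1), seed=5)
        profile = interactions.contact_profile(traj, [1])
        assert profile.backbone_probability.max() == 0.0
        assert profile.important_backbone == []
        assert profile.important_sidechain == []


class TestOccupancy:
    def test_present_every_frame(self, ordered_dimer):
        traj = synth.generate_trajectory(ordered_dimer,
                                         synth.DisorderSpec(), 4)
        occ = interactions.hbond_occupancy(traj, ("B", 5, "N"), ("A", 5, "O"),
                                           scope="backbone")
        assert occ == 1.0

    def test_partial_occupancy_counting(self, ordered_dimer):
        base = synth.generate_trajectory(ordered_dimer,
                                         synth.DisorderSpec(), 10)
        top = base.topology
        amide = [top.atom_index("B", 5, "N"), top.atom_index("B", 5, "H")]
        frames = []
        for i, f in enumerate(base.frames):
            c = f.coordinates.copy()
            if i >= 4:
                c[amide] += np.array([0.0, 2.5, 0.0])
            frames.append(Frame(c, f.time))
        traj = Trajectory(top, frames)
        occ = interactions.hbond_occupancy(traj, ("B", 5, "N"), ("A", 5, "O"),
                                           scope="backbone")
        assert occ == pytest.approx(0.4)


class TestPiStacking:
    def hexagon(self, center, normal_tilt=0.0):
        pts = []
        for k in range(6):
            ang = np.radians(60 * k)
            p = np.array([1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0])
            tilt = np.array([[1, 0, 0],
                             [0, np.cos(normal_tilt), -np.sin(normal_tilt)],
                             [0, np.sin(normal_tilt), np.cos(normal_tilt)]])
            pts.append(tilt @ p + center)
        return np.array(pts)

    def frame_with_rings(self, *rings):
        coords = np.vstack(rings)
        return Frame(coords), [list(range(6 * i, 6 * i + 6))
                               for i in range(len(rings))]

    def test_parallel_stack(self):
        frame, (ra, rb) = self.frame_with_rings(
            self.hexagon([0, 0, 0]), self.hexagon([0, 0, 3.8]))
        out = interactions.pi_stacking(frame, [ra], [rb])
        assert len(out) == 1
        assert out[0].geometry == "parallel"
        assert out[0].centroid_distance == pytest.approx(3.8)

    def test_perpendicular_stack(self):
        frame, (ra, rb) = self.frame_with_rings(
            self.hexagon([0, 0, 0]),
            self.hexagon([0, 0, 5.0], normal_tilt=np.pi / 2))
        out = interactions.pi_stacking(frame, [ra], [rb])
        assert out[0].geometry == "perpendicular"

    def test_beyond_cutoff_not_reported(self):
        frame, (ra, rb) = self.frame_with_rings(
            self.hexagon([0, 0, 0]), self.hexagon([0, 0, 6.0]))
        assert interactions.pi_stacking(frame, [ra], [rb]) == []

    def test_small_ring_rejected(self):
        frame, (ra, rb) = self.frame_with_rings(
            self.hexagon([0, 0, 0]), self.hexagon([0, 0, 3.0]))
        with pytest.raises(ValueError, match="3 atoms"):
            interactions.pi_stacking(frame, [ra[:2]], [rb])


def charged_pair(r, q=1.0, eps=0.0, rmin_half=1.0):
    atoms = [
        AtomRecord(serial=1, name="C1", element="C", chain_id="A",
                   residue_index=1, residue_name="ION", charge=q,
                   lj_epsilon=eps, lj_rmin_half=rmin_half),
        AtomRecord(serial=2, name="C1", element="C", chain_id="B",
                   residue_index=1, residue_name="ION", charge=q,
                   lj_epsilon=eps, lj_rmin_half=rmin_half),
    ]
    top = Topology(atoms)
    frame = Frame(np.array([[0.0, 0, 0], [r, 0, 0]]))
    return Trajectory(top, [frame]), np.array([0]), np.array([1])


class TestEnergy:
    def test_coulomb_closed_form(self):
        traj, a, b = charged_pair(5.0)
        trace = interactions.interaction_energy(traj, a, b)
        assert trace.electrostatic[0] == pytest.approx(332.0636 / 5.0)
        assert trace.vdw[0] == 0.0
        assert trace.total[0] == trace.vdw[0] + trace.electrostatic[0]

    def test_beyond_switch_cutoff_is_zero(self):
        traj, a, b = charged_pair(12.0)
        assert interactions.interaction_energy(traj, a, b).total[0] == 0.0
        traj, a, b = charged_pair(14.0)
        assert interactions.interaction_energy(traj, a, b).total[0] == 0.0

    def test_lj_minimum_depth(self):
        traj, a, b = charged_pair(2.0, q=0.0, eps=0.25, rmin_half=1.0)
        trace = interactions.interaction_energy(traj, a, b)
        assert trace.vdw[0] == pytest.approx(-0.25)  # r == Rmin_ij -> -eps

    def test_symmetry(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(seed=1), 2)
        traj = synth.place_ligands(
            traj, synth.LigandPlacement(site=[("B", 26)], n_copies=1), seed=2)
        top = traj.topology
        prot = np.flatnonzero(top.protein_mask)
        lig = np.flatnonzero(top.is_ligand_mask)
        ab = interactions.interaction_energy(traj, prot, lig)
        ba = interactions.interaction_energy(traj, lig, prot)
        np.testing.assert_allclose(ab.total, ba.total, atol=1e-9)

    def test_empty_group_gives_zero_trace(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 2)
        trace = interactions.interaction_energy(traj, np.array([0, 1]),
                                                np.array([], dtype=int))
        np.testing.assert_array_equal(trace.total, [0.0, 0.0])

    def test_missing_parameters_listed(self):
        atoms = [
            AtomRecord(serial=1, name="CA", element="C", chain_id="A",
                       residue_index=1, residue_name="ALA"),
            AtomRecord(serial=2, name="CA", element="C", chain_id="B",
                       residue_index=1, residue_name="ALA", charge=0.0,
                       lj_epsilon=0.1, lj_rmin_half=1.0),
        ]
        traj = Trajectory(Topology(atoms), [Frame(np.zeros((2, 3)))])
        with pytest.raises(ValueError, match="A:1:CA"):
            interactions.interaction_energy(traj, np.array([0]), np.array([1]))


class TestSwitchingFunction:
    def test_plateaus(self):
        assert interactions.switching_function(5.0) == 1.0
        assert interactions.switching_function(12.0) == 0.0
        assert interactions.switching_function(20.0) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(9.99, 12.01))
    def test_smooth_and_monotone(self, r):
        s = interactions.switching_function(r)
        assert 0.0 <= s <= 1.0

    def test_continuity_at_bounds(self):
        eps = 1e-7
        for r0 in (10.0, 12.0):
            lo = interactions.switching_function(r0 - eps)
            hi = interactions.switching_function(r0 + eps)
            assert abs(lo - hi) < 1e-5
            dlo = (interactions.switching_function(r0 - eps)
                   - interactions.switching_function(r0 - 2 * eps)) / eps
            dhi = (interactions.switching_function(r0 + 2 * eps)
                   - interactions.switching_function(r0 + eps)) / eps
            assert abs(dlo - dhi) < 1e-3
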