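"""Nematic order parameter, superposition/RMSD, RMSF and Rg."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligodestab import order, synth
from oligodestab.model import Frame, Trajectory

from conftest import make_ca_chains


def random_rotation(rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, 2 * np.pi)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestNematicP2:
    def test_identical_vectors_give_one(self):
        top, frame = make_ca_chains(np.tile([0.0, 0.0, 1.0], (5, 1)))
        result = order.nematic_p2(frame, top)
        assert result.p2 == pytest.approx(1.0, abs=1e-9)
        assert result.n_chains == 5

    def test_two_perpendicular_chains(self):
        """Hand eigendecomposition: Q = diag(1/4, 1/4, -1/2) -> P2 = 0.25."""
        top, frame = make_ca_chains(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        result = order.nematic_p2(frame, top)
        assert result.p2 == pytest.approx(0.25, abs=1e-9)

    def test_random_orientations_classified_disordered(self):
        rng = np.random.default_rng(11)
        u = rng.normal(size=(1000, 3))
        top, frame = make_ca_chains(u)
        assert order.nematic_p2(frame, top).p2 < 0.5

    def test_rotation_and_flip_invariance(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(8, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        p2 = order.nematic_p2_from_vectors(u).p2
        rot = random_rotation(rng)
        assert order.nematic_p2_from_vectors(u @ rot.T).p2 == pytest.approx(p2, abs=1e-9)
        flipped = u.copy()
        flipped[3] *= -1
        assert order.nematic_p2_from_vectors(flipped).p2 == pytest.approx(p2, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_eigendirector_maximizes_p2(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(6, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        res = order.nematic_p2_from_vectors(u)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            other = np.mean(1.5 * (u @ d) ** 2 - 0.5)
            assert other <= res.p2 + 1e-9

    def test_missing_terminal_calpha_names_chain(self, ordered_pentamer):
        top = ordered_pentamer.topology
        # drop all chain C C-alphas
        keep = ~((top.chain_ids == "C") & top.calpha_mask)
        from oligodestab.model import Topology
        sub = Topology([a for a, k in zip(top.atoms, keep) if k])
        frame = Frame(ordered_pentamer.frame.coordinates[keep])
        with pytest.raises(ValueError, match="chain C"):
            order.nematic_p2(frame, sub)


class TestClassifyOrder:
    def test_constant_series(self):
        label, mean, sd = order.classify_order([0.62] * 5)
        assert (label, mean, sd) == ("ordered", pytest.approx(0.62), 0.0)

    def test_boundary_is_strict(self):
        label, _, _ = order.classify_order([0.50, 0.50])
        assert label == "disordered"

    def test_mean_arithmetic(self):
        label, mean, _ = order.classify_order([0.4, 0.8])
        assert label == "ordered"
        assert mean == pytest.approx(0.6)


class TestSuperpose:
    def test_translation_removed(self, ordered_pentamer):
        top = ordered_pentamer.topology
        sel = np.flatnonzero(top.calpha_mask)
        ref = ordered_pentamer.frame
        moved = Frame(ref.coordinates + np.array([5.0, 0, 0]))
        _, rmsd = order.superpose(moved, ref, sel)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_identity(self, ordered_pentamer):
        sel = np.flatnonzero(ordered_pentamer.topology.calpha_mask)
        fitted, rmsd = order.superpose(ordered_pentamer.frame,
                                       ordered_pentamer.frame, sel)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fitted.coordinates,
                                   ordered_pentamer.frame.coordinates,
                                   atol=1e-9)

    def test_toy_displacement_matches_rotation_grid_oracle(self):
        """4-atom toy: Kabsch result equals the brute-force minimum over a
        rotation grid and never exceeds the fit-leaves-displacement value."""
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        mob = ref.copy()
        mob[3] += np.array([0.0, 0.0, 1.0])
        sel = np.arange(4)
        _, rmsd = order.superpose(Frame(mob), Frame(ref), sel)
        assert rmsd <= 0.5 + 1e-12  # sqrt(1/4) if the fit kept the rest exact

        def grid_min():
            best = np.inf
            x = mob - mob.mean(axis=0)
            y = ref - ref.mean(axis=0)
            angles = np.linspace(0, 2 * np.pi, 60, endpoint=False)
            for a in angles:
                for b in angles[:30]:
                    for c in angles:
                        ca_, sa = np.cos(a), np.sin(a)
                        cb, sb = np.cos(b), np.sin(b)
                        cc, sc = np.cos(c), np.sin(c)
                        rz1 = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
                        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
                        rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
                        r = rz1 @ ry @ rz2
                        val = np.sqrt(np.mean(np.sum((x @ r.T - y) ** 2, axis=1)))
                        best = min(best, val)
            return best

        assert rmsd <= grid_min() + 1e-6

    def test_symmetry(self, ordered_pentamer):
        rng = np.random.default_rng(2)
        top = ordered_pentamer.topology
        sel = np.flatnonzero(top.calpha_mask)
        a = ordered_pentamer.frame
        b = Frame(a.coordinates + rng.normal(0, 0.5, a.coordinates.shape))
        _, rab = order.superpose(a, b, sel)
        _, rba = order.superpose(b, a, sel)
        assert rab == pytest.approx(rba, abs=1e-9)

    def test_too_few_atoms(self, ordered_pentamer):
        with pytest.raises(ValueError, match="3"):
            order.superpose(ordered_pentamer.frame, ordered_pentamer.frame,
                            np.array([0, 1]))


class TestRMSF:
    def test_static_trajectory_is_zero(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 5)
        fitted, _ = order.superpose_trajectory(traj)
        rmsf = order.rmsf_per_residue_chain_averaged(fitted)
        np.testing.assert_allclose(rmsf, 0.0, atol=1e-9)

    def test_single_oscillating_residue_divided_by_chains(self, ordered_pentamer):
        """Residue 30 of one of five chains oscillating +/-1 A -> chain-averaged
        RMSF at residue 30 equals 1/5 A."""
        top = ordered_pentamer.topology
        base = ordered_pentamer.frame.coordinates
        target = top.atom_index("A", 30, "CA")
        frames = []
        for i in range(4):
            c = base.copy()
            c[target, 0] += 1.0 if i % 2 == 0 else -1.0
            frames.append(Frame(c, float(i)))
        traj = Trajectory(top, frames, superposed=True)
        rmsf = order.rmsf_per_residue_chain_averaged(traj)
        assert rmsf[29] == pytest.approx(0.2, abs=1e-9)
        assert rmsf[10] == pytest.approx(0.0, abs=1e-9)

    def test_refuses_unsuperposed(self, ordered_pentamer):
        traj = synth.generate_trajectory(ordered_pentamer,
                                         synth.DisorderSpec(), 3)
        with pytest.raises(ValueError, match="superposed"):
            order.rmsf_per_residue_chain_averaged(traj)


class TestRadiusOfGyration:
    def test_two_atoms(self):
        frame = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert order.radius_of_gyration(frame, np.array([0, 1])) == pytest.approx(1.0)

    def test_single_atom(self):
        frame = Frame(np.array([[3.0, 1, 2]]))
        assert order.radius_of_gyration(frame, np.array([0])) == 0.0

    def test_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 2.0)
                            for y in (0, 2.0) for z in (0, 2.0)])
        frame = Frame(corners)
        assert order.radius_of_gyration(frame, np.arange(8)) == pytest.approx(np.sqrt(3))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_translation_invariance_and_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3))
        sel = np.arange(10)
        rg = order.radius_of_gyration(Frame(pts), sel)
        shifted = order.radius_of_gyration(Frame(pts + 100.0), sel)
        scaled = order.radius_of_gyration(Frame(pts * scale), sel)
        assert shifted == pytest.approx(rg, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(rg * scale, rel=1e-9)
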