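"""Mode editing, comparison, matching, projection and traversal."""

import itertools

import numpy as np
import pytest

import flexkit as fk


class TestSliceExtend:
    def test_slice_to_all_atoms_is_identity(self, dumbbell, dumbbell_anm):
        sel = fk.select_atoms(dumbbell, "protein")
        out = fk.slice_modes(dumbbell_anm, sel)
        np.testing.assert_allclose(out.vectors, dumbbell_anm.vectors,
                                   atol=1e-12)

    def test_extend_then_slice_round_trip(self, dumbbell, dumbbell_anm):
        """Cα → all-atom extension sliced back to Cα restores the modes."""
        # build an all-atom stand-in: 4 pseudo-atoms per residue
        atoms = []
        serial = 1
        for a in dumbbell.atoms:
            for name in ("N", "CA", "C", "O"):
                b = a.copy()
                b.serial = serial
                b.name = name
                atoms.append(b)
                serial += 1
        target = fk.Structure(atoms, title="all-atom")
        extended = fk.extend_modes(dumbbell_anm, target)
        back = fk.slice_modes(extended, fk.select_atoms(target, "name CA"))
        np.testing.assert_allclose(back.vectors, dumbbell_anm.vectors,
                                   atol=1e-10)

    def test_extended_vectors_constant_per_residue(self, dumbbell,
                                                   dumbbell_anm):
        atoms = []
        for a in dumbbell.atoms:
            for name in ("N", "CA", "C", "O", "CB"):
                b = a.copy()
                b.name = name
                atoms.append(b)
        target = fk.Structure(atoms)
        ext = fk.extend_modes(dumbbell_anm, target)
        per_atom = ext.vectors.reshape(len(target), 3, ext.n_modes)
        groups = per_atom.reshape(len(dumbbell), 5, 3, ext.n_modes)
        assert np.abs(groups - groups[:, :1]).max() < 1e-12

    def test_two_residue_construction(self):
        source = fk.Structure([
            fk.Atom(1, "CA", "", "ALA", "A", 1, "", np.array([0.0, 0, 0])),
            fk.Atom(2, "CA", "", "ALA", "A", 2, "", np.array([3.8, 0, 0]))])
        vec = np.array([1.0, 0, 0, 0, 1.0, 0])[:, None]
        ms = fk.ModeSet(vec, np.array([1.0]), kind="anm",
                        source_atoms=source)
        atoms = []
        for a in source.atoms:
            for name in ("N", "CA", "C", "O", "CB"):
                b = a.copy()
                b.name = name
                atoms.append(b)
        ext = fk.extend_modes(ms, fk.Structure(atoms))
        col = ext.vectors[:, 0].reshape(10, 3)
        np.testing.assert_allclose(col[:5], [[1.0, 0, 0]] * 5)
        np.testing.assert_allclose(col[5:], [[0, 1.0, 0]] * 5)

    def test_unmatched_residue_rejected(self, dumbbell, dumbbell_anm):
        extra = dumbbell.copy()
        extra.atoms.append(fk.Atom(999, "CA", "", "ALA", "Z", 1, "",
                                   np.zeros(3)))
        with pytest.raises(ValueError, match="no source"):
            fk.extend_modes(dumbbell_anm, extra)

    def test_empty_slice_rejected(self, dumbbell, dumbbell_anm):
        sel = fk.select_atoms(dumbbell, "not protein")
        with pytest.raises(ValueError):
            fk.slice_modes(dumbbell_anm, sel)


class TestReduceHessian:
    def test_decoupled_limit_returns_subsystem_block(self, coil):
        far = coil.coords + np.array([500.0, 0, 0])
        coords = np.vstack([coil.coords, far])
        h = fk.build_hessian(fk.ElasticModel(coords, cutoff=15.0))
        n = len(coil)
        heff = fk.reduce_hessian(h, np.arange(n))
        np.testing.assert_allclose(heff, h[:3 * n, :3 * n], atol=1e-10)

    def test_three_atom_chain_schur_complement(self):
        """Reducing out the middle atom matches the explicit Schur formula."""
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        h = fk.build_hessian(fk.ElasticModel(coords, cutoff=5.0))
        sub = np.array([0, 2])
        heff = fk.reduce_hessian(h, sub)
        dof_s = np.array([0, 1, 2, 6, 7, 8])
        dof_e = np.array([3, 4, 5])
        hss = h[np.ix_(dof_s, dof_s)]
        hse = h[np.ix_(dof_s, dof_e)]
        hee = h[np.ix_(dof_e, dof_e)]
        oracle = hss - hse @ np.linalg.pinv(hee) @ hse.T
        np.testing.assert_allclose(heff, oracle, atol=1e-10)

    def test_environment_softens_subsystem(self, dumbbell):
        """The effective Hessian is softer than the bare subsystem block
        (the Schur complement subtracts a PSD term from H_ss)."""
        coords = dumbbell.coords
        n = len(dumbbell)
        h = fk.build_hessian(fk.ElasticModel(coords, cutoff=15.0))
        sub = np.arange(n // 2)
        dof = (3 * sub[:, None] + np.arange(3)).ravel()
        hss = h[np.ix_(dof, dof)]
        heff = fk.reduce_hessian(h, sub)
        eig_eff = np.linalg.eigvalsh(heff)
        eig_ss = np.linalg.eigvalsh(hss)
        assert np.all(eig_eff <= eig_ss + 1e-9)  # Weyl: H_eff ⪯ H_ss
        assert eig_eff.min() >= -1e-9

    def test_whole_structure_subsystem_warns(self, coil):
        h = fk.build_hessian(fk.ElasticModel(coil.coords, cutoff=15.0))
        with pytest.warns(UserWarning, match="whole"):
            out = fk.reduce_hessian(h, np.arange(len(coil)))
        np.testing.assert_allclose(out, h)


def dense_tps_solve(nodes, values, targets):
    """Independent dense thin-plate solve: U(r) = r kernel + affine term."""
    p = nodes.shape[0]
    k = np.linalg.norm(nodes[:, None] - nodes[None], axis=2)
    poly = np.hstack([np.ones((p, 1)), nodes])
    lhs = np.block([[k, poly], [poly.T, np.zeros((4, 4))]])
    rhs = np.vstack([values, np.zeros((4, values.shape[1]))])
    sol = np.linalg.solve(lhs, rhs)
    kt = np.linalg.norm(targets[:, None] - nodes[None], axis=2)
    polyt = np.hstack([np.ones((targets.shape[0], 1)), targets])
    return kt @ sol[:p] + polyt @ sol[p:]


class TestTPS:
    def test_identity_at_source_nodes(self):
        rng = np.random.default_rng(0)
        nodes = rng.uniform(-10, 10, (10, 3))
        vecs = rng.standard_normal((30, 3))
        out = fk.interpolate_modes_tps(nodes, vecs, nodes)
        np.testing.assert_allclose(out, vecs, atol=1e-8)

    def test_affine_field_reproduced_everywhere(self):
        rng = np.random.default_rng(1)
        nodes = rng.uniform(-10, 10, (8, 3))
        targets = rng.uniform(-10, 10, (20, 3))
        a = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        field = nodes @ a.T + b
        out = fk.interpolate_modes_tps(nodes, field.reshape(-1, 1)
                                       .reshape(24, 1), targets)
        expected = (targets @ a.T + b).reshape(-1, 1)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_matches_dense_linear_system_oracle(self):
        rng = np.random.default_rng(2)
        nodes = rng.uniform(-10, 10, (10, 3))
        values = rng.standard_normal((10, 3))
        targets = rng.uniform(-10, 10, (15, 3))
        ours = fk.interpolate_modes_tps(nodes, values.reshape(30, 1),
                                        targets)
        # scipy's "linear" RBF kernel is −r; the sign flip cancels in the
        # solve, so the oracle uses +r directly
        oracle = dense_tps_solve(nodes, values, targets)
        np.testing.assert_allclose(ours.reshape(15, 3), oracle, atol=1e-8)

    def test_degenerate_nodes_rejected(self):
        flat = np.hstack([np.random.default_rng(3).uniform(-5, 5, (6, 2)),
                          np.zeros((6, 1))])
        with pytest.raises(ValueError, match="coplanar"):
            fk.interpolate_modes_tps(flat, np.zeros((18, 1)), flat)


class TestCompareModes:
    def test_self_comparison_is_identity(self, dumbbell_anm):
        out = fk.compare_modes(dumbbell_anm, dumbbell_anm)
        np.testing.assert_allclose(out.matrix,
                                   np.eye(dumbbell_anm.n_modes), atol=1e-8)

    def test_parseval_cumulative_overlap(self, coil):
        """Any unit vector vs a complete orthonormal basis accumulates to 1."""
        h = fk.build_hessian(fk.ElasticModel(coil.coords, cutoff=15.0))
        full = fk.solve_modes(h, n_modes=3 * len(coil), skip_zeros=False)
        rng = np.random.default_rng(5)
        v = rng.standard_normal(3 * len(coil))
        v /= np.linalg.norm(v)
        probe = fk.ModeSet(v[:, None], np.array([1.0]), kind="anm")
        out = fk.compare_modes(probe, full)
        assert out.row_cumulative[0] == pytest.approx(1.0, abs=1e-8)

    def test_rwsip_and_cov_overlap_self_identity(self, dumbbell_anm):
        assert fk.compare_modes(dumbbell_anm, dumbbell_anm,
                                "rwsip").value == pytest.approx(1.0)
        assert fk.compare_modes(dumbbell_anm, dumbbell_anm,
                                "cov_overlap").value == pytest.approx(1.0)

    def test_rotated_2d_bases(self):
        theta = 0.4
        e1 = np.array([1.0, 0, 0, 0, 0, 0])
        e2 = np.array([0, 1.0, 0, 0, 0, 0])
        r1 = np.cos(theta) * e1 + np.sin(theta) * e2
        r2 = -np.sin(theta) * e1 + np.cos(theta) * e2
        a = fk.ModeSet(np.column_stack([e1, e2]), np.array([1.0, 2.0]),
                       kind="anm")
        b = fk.ModeSet(np.column_stack([r1, r2]), np.array([1.0, 2.0]),
                       kind="anm")
        out = fk.compare_modes(a, b)
        np.testing.assert_allclose(
            out.matrix,
            [[np.cos(theta), np.sin(theta)],
             [np.sin(theta), np.cos(theta)]], atol=1e-12)

    def test_signed_raw_products_option(self, dumbbell_anm):
        flipped = fk.ModeSet(-dumbbell_anm.vectors,
                             dumbbell_anm.eigenvalues.copy(), kind="anm")
        raw = fk.compare_modes(dumbbell_anm, flipped, normalise=False)
        assert np.allclose(np.diag(raw.matrix), -1.0, atol=1e-8)

    def test_dimension_mismatch_advises_editing(self, dumbbell_anm):
        small = fk.ModeSet(np.eye(6), np.ones(6), kind="anm")
        with pytest.raises(ValueError, match="slice or"):
            fk.compare_modes(dumbbell_anm, small)


class TestMatchModes:
    def test_identity_overlap(self):
        o = fk.OverlapResult(np.eye(4), "overlap", np.ones(4))
        match = fk.match_modes(o)
        np.testing.assert_array_equal(match.permutation, np.arange(4))

    def test_permuted_self_overlap_recovers_inverse(self, dumbbell_anm):
        perm = np.array([2, 0, 1, 3, 5, 4])
        shuffled = fk.ModeSet(dumbbell_anm.vectors[:, perm],
                              dumbbell_anm.eigenvalues[perm], kind="anm")
        o = fk.compare_modes(dumbbell_anm, shuffled)
        match = fk.match_modes(o, shuffled)
        np.testing.assert_array_equal(match.permutation, np.argsort(perm))
        np.testing.assert_allclose(np.abs(match.reordered.vectors),
                                   np.abs(dumbbell_anm.vectors), atol=1e-10)

    def test_random_matrix_equals_exhaustive_search(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = rng.uniform(0, 1, (5, 5))
            o = fk.OverlapResult(m, "overlap", np.ones(5))
            got = fk.match_modes(o).permutation
            best, best_score = None, -1.0
            for perm in itertools.permutations(range(5)):
                score = sum(m[i, p] ** 2 for i, p in enumerate(perm))
                if score > best_score:
                    best, best_score = perm, score
            got_score = sum(m[i, p] ** 2 for i, p in enumerate(got))
            assert got_score == pytest.approx(best_score)


class TestProjection:
    def test_mean_structure_projects_to_origin(self, spike_states):
        ens = fk.build_ensemble(spike_states, reference=0)
        ms = fk.compute_pca(ens, 2)
        mean_member = fk.StructEnsemble(
            ["mean"], ens.mean_coords[None], np.ones((1, ens.n_atoms)),
            ens.reference_atoms, ["-"], ens.mean_coords)
        proj = fk.project_ensemble(mean_member, ms)
        np.testing.assert_allclose(proj.coords, 0.0, atol=1e-8)

    def test_intermediate_state_near_zero_on_pc1(self, spike_states):
        """The 1-up analogue sits near the origin of PC1; the 3-down and
        2-up analogues are the extremes."""
        ens = fk.build_ensemble(spike_states, reference=0)
        ms = fk.compute_pca(ens, 2)
        proj = fk.project_ensemble(ens, ms, scaling="rmsd")
        pc1 = proj.coords[:, 0]
        order = np.argsort(np.abs(pc1))
        assert ens.labels[order[0]] == "1up"
        assert {ens.labels[i] for i in order[1:]} == {"3down", "2up"}
        assert np.sign(pc1[ens.labels.index("3down")]) != \
            np.sign(pc1[ens.labels.index("2up")])


class TestTraverse:
    def test_zero_rmsd_rejected(self, dumbbell, dumbbell_anm):
        with pytest.raises(ValueError):
            fk.traverse_mode(dumbbell, dumbbell_anm, rmsd=0.0)

    def test_end_frame_rmsd_exact(self, dumbbell, dumbbell_anm):
        frames = fk.traverse_mode(dumbbell, dumbbell_anm, rmsd=2.0,
                                  n_frames=7)
        n = len(dumbbell)
        end = frames[-1].coords
        rmsd = np.sqrt(((end - dumbbell.coords) ** 2).sum() / n)
        assert rmsd == pytest.approx(2.0, abs=1e-10)
        mid = frames[3].coords
        np.testing.assert_allclose(mid, dumbbell.coords, atol=1e-10)

    def test_traversal_displacement_parallel_to_mode(self, dumbbell,
                                                     dumbbell_anm):
        frames = fk.traverse_mode(dumbbell, dumbbell_anm, rmsd=2.0,
                                  n_frames=5, direction="pos")
        dv = fk.deformation_vector(frames[0].coords, frames[-1].coords)
        u = dumbbell_anm.vectors[:, 0]
        cos = abs(dv.vector @ u) / np.linalg.norm(dv.vector)
        assert cos > 1 - 1e-9
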