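"""UPGMA clustering, GNM domains and the hybrid sampling loop."""

import numpy as np
import pytest

import flexkit as fk


def brute_force_upgma(d):
    """Independent UPGMA: explicit average-linkage agglomeration."""
    d = d.astype(float).copy()
    m = d.shape[0]
    clusters = {i: [i] for i in range(m)}
    active = list(range(m))
    merges = []
    next_id = m
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1:]:
                dist = np.mean([d[x, y] for x in clusters[a]
                                for y in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((min(a, b), max(a, b), dist,
                       len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


class TestUPGMA:
    def test_two_members_single_merge(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = fk.upgma_cluster(d)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(3.0)

    def test_ultrametric_heights_recovered(self):
        """On an ultrametric matrix UPGMA reproduces the exact heights."""
        # pairs (0,1) at 2, (2,3) at 4, the two groups at 10
        d = np.array([[0.0, 2, 10, 10],
                      [2, 0.0, 10, 10],
                      [10, 10, 0.0, 4],
                      [10, 10, 4, 0.0]])
        tree = fk.upgma_cluster(d)
        heights = sorted(tree.linkage[:, 2])
        assert heights == pytest.approx([2.0, 4.0, 10.0])

    def test_random_matrices_match_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.uniform(1, 10, (6, 6))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = fk.upgma_cluster(d)
            oracle = brute_force_upgma(d)
            np.testing.assert_allclose(sorted(tree.linkage[:, 2]),
                                       sorted(h for *_, h, _ in
                                              [(a, b, h, s) for a, b, h, s
                                               in oracle]), atol=1e-10)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fk.upgma_cluster(d)


class TestCutTree:
    def _tree(self):
        rng = np.random.default_rng(0)
        centers = np.array([0.0, 5.0, 10.0])
        vals = np.repeat(centers, 4) + rng.uniform(-0.4, 0.4, 12)
        d = np.abs(vals[:, None] - vals[None, :])
        return fk.upgma_cluster(d), vals

    def test_cutoff_below_min_height_gives_singletons(self):
        tree, _ = self._tree()
        clusters, reps = fk.cut_tree(tree, cutoff=1e-6)
        assert len(clusters) == 12
        assert reps == [c[0] for c in clusters]

    def test_cutoff_above_max_height_gives_one_cluster(self):
        tree, _ = self._tree()
        clusters, reps = fk.cut_tree(tree, cutoff=100.0)
        assert len(clusters) == 1 and len(clusters[0]) == 12

    def test_planted_three_clusters_with_medoid_reps(self):
        tree, vals = self._tree()
        clusters, reps = fk.cut_tree(tree, cutoff=2.5)
        assert len(clusters) == 3
        for members, rep in zip(clusters, reps):
            assert rep in members
            # medoid: lowest mean distance to co-members
            sub = np.abs(vals[members][:, None] - vals[members][None])
            assert vals[rep] == vals[members][np.argmin(sub.mean(1))]

    def test_ultrametric_cut_equals_threshold_clustering(self):
        d = np.array([[0.0, 2, 10, 10],
                      [2, 0.0, 10, 10],
                      [10, 10, 0.0, 4],
                      [10, 10, 4, 0.0]])
        tree = fk.upgma_cluster(d)
        clusters, _ = fk.cut_tree(tree, cutoff=5.0)
        assert sorted(map(sorted, clusters)) == [[0, 1], [2, 3]]


class TestGNMDomains:
    def test_disconnected_components_split_exactly(self, coil):
        far = coil.coords + np.array([500.0, 0, 0])
        coords = np.vstack([coil.coords, far])
        k = fk.build_kirchhoff(fk.ElasticModel(coords, cutoff=10.0,
                                               kind="gnm"))
        # keep the zero modes: they are the component indicators
        ms = fk.solve_modes(k, n_modes=2, kind="gnm", skip_zeros=False)
        out = fk.gnm_domains(ms, n_modes=2, n_domains=2)
        n = len(coil)
        assert len(set(out.labels[:n])) == 1
        assert len(set(out.labels[n:])) == 1
        assert out.labels[0] != out.labels[-1]

    def test_two_lobe_fixture_splits_at_mode_sign_change(self, dumbbell):
        """Domains from one slow mode separate regions moving oppositely."""
        k = fk.build_kirchhoff(fk.ElasticModel(dumbbell.coords, cutoff=10.0,
                                               kind="gnm"))
        ms = fk.solve_modes(k, n_modes=1, kind="gnm")
        out = fk.gnm_domains(ms, n_modes=1, n_domains=2)
        shape = ms.vectors[:, 0]
        sign_split = (shape > 0).astype(int)
        agreement = max(np.mean(out.labels == sign_split),
                        np.mean(out.labels == 1 - sign_split))
        assert agreement == 1.0

    def test_labels_invariant_under_reordering(self, dumbbell):
        k = fk.build_kirchhoff(fk.ElasticModel(dumbbell.coords, cutoff=10.0,
                                               kind="gnm"))
        ms = fk.solve_modes(k, n_modes=2, kind="gnm")
        base = fk.gnm_domains(ms, 2, 2).labels
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(dumbbell))
        ms_p = fk.ModeSet(ms.vectors[perm], ms.eigenvalues.copy(),
                          kind="gnm")
        permuted = fk.gnm_domains(ms_p, 2, 2).labels
        # equal up to relabelling
        mapping = {}
        ok = True
        for a, b in zip(base[perm], permuted):
            mapping.setdefault(a, b)
            ok &= mapping[a] == b
        assert ok

    def test_too_many_domains_rejected(self, dumbbell):
        k = fk.build_kirchhoff(fk.ElasticModel(dumbbell.coords, cutoff=10.0,
                                               kind="gnm"))
        ms = fk.solve_modes(k, n_modes=2, kind="gnm")
        with pytest.raises(ValueError):
            fk.gnm_domains(ms, 2, len(dumbbell) + 1)


class TestSampleConformers:
    def test_reproducible_under_fixed_seed(self, dumbbell, dumbbell_anm):
        a = fk.sample_conformers(dumbbell, dumbbell_anm, 3, 2.0, 4,
                                 np.random.default_rng(5))
        b = fk.sample_conformers(dumbbell, dumbbell_anm, 3, 2.0, 4,
                                 np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)

    def test_rmsd_exactly_at_target(self, dumbbell, dumbbell_anm):
        confs = fk.sample_conformers(dumbbell, dumbbell_anm, 10, 2.0, 4,
                                     np.random.default_rng(0))
        n = len(dumbbell)
        for c in confs:
            rmsd = np.sqrt(((c.coords - dumbbell.coords) ** 2).sum() / n)
            assert rmsd == pytest.approx(2.0, abs=1e-9)

    def test_displacement_confined_to_mode_subspace(self, dumbbell,
                                                    dumbbell_anm):
        confs = fk.sample_conformers(dumbbell, dumbbell_anm, 5, 2.0, 3,
                                     np.random.default_rng(2))
        u = dumbbell_anm.vectors[:, :3]
        for c in confs:
            disp = (c.coords - dumbbell.coords).ravel()
            residual = disp - u @ (u.T @ disp)
            assert np.linalg.norm(residual) < 1e-9

    def test_sampled_rmsd_mode_stays_in_band(self, dumbbell, dumbbell_anm):
        confs = fk.sample_conformers(dumbbell, dumbbell_anm, 50, 2.0, 3,
                                     np.random.default_rng(3),
                                     rmsd_mode="sampled")
        n = len(dumbbell)
        rmsds = [np.sqrt(((c.coords - dumbbell.coords) ** 2).sum() / n)
                 for c in confs]
        assert min(rmsds) >= 1.0 - 1e-9 and max(rmsds) <= 3.0 + 1e-9

    def test_isotropy_in_mode_subspace(self, dumbbell, dumbbell_anm):
        """Direction cosines over many conformers average to zero and
        spread evenly across the sampled modes."""
        confs = fk.sample_conformers(dumbbell, dumbbell_anm, 1000, 2.0, 4,
                                     np.random.default_rng(4))
        u = dumbbell_anm.vectors[:, :4]
        dirs = []
        for c in confs:
            disp = (c.coords - dumbbell.coords).ravel()
            coeffs = u.T @ disp
            dirs.append(coeffs / np.linalg.norm(coeffs))
        dirs = np.array(dirs)
        assert np.abs(dirs.mean(axis=0)).max() < 4 / np.sqrt(1000)
        second = (dirs ** 2).mean(axis=0)
        np.testing.assert_allclose(second, 0.25, atol=0.05)

    def test_invalid_inputs(self, dumbbell, dumbbell_anm):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            fk.sample_conformers(dumbbell, dumbbell_anm, 1, -1.0, 3, rng)
        with pytest.raises(ValueError):
            fk.sample_conformers(dumbbell, dumbbell_anm, 1, 2.0, 99, rng)


class TestClusterGeneration:
    def _confs(self, dumbbell, dumbbell_anm, k, rmsd=2.0):
        return fk.sample_conformers(dumbbell, dumbbell_anm, k, rmsd, 4,
                                    np.random.default_rng(8))

    def test_small_pool_kept_entirely(self, dumbbell, dumbbell_anm):
        confs = self._confs(dumbbell, dumbbell_anm, 4)
        assert fk.cluster_generation(confs, 10) == confs

    def test_single_cluster_returns_medoid(self, dumbbell, dumbbell_anm):
        confs = self._confs(dumbbell, dumbbell_anm, 6)
        reps = fk.cluster_generation(confs, 1)
        assert len(reps) == 1 and reps[0] in confs

    def test_planted_clusters_one_rep_each(self, dumbbell, dumbbell_anm):
        rng = np.random.default_rng(9)
        u = dumbbell_anm.vectors[:, :3]
        n = len(dumbbell)
        pools, truth = [], []
        for ci in range(3):
            center = u @ rng.standard_normal(3)
            center *= 8.0 * np.sqrt(n) / np.linalg.norm(center)
            for _ in range(4):
                wiggle = u @ rng.standard_normal(3)
                wiggle *= 0.5 * np.sqrt(n) / np.linalg.norm(wiggle)
                c = dumbbell.copy()
                c.title = f"c{ci}"
                c.set_coords(dumbbell.coords
                             + (center + wiggle).reshape(n, 3))
                pools.append(c)
                truth.append(ci)
        reps = fk.cluster_generation(pools, 3)
        assert sorted(r.title for r in reps) == ["c0", "c1", "c2"]


class TestHybridRun:
    def test_zero_generations_identity_relaxer(self, dumbbell):
        cfg = fk.HybridConfig(n_generations=0, max_clusters=[], seed=1)
        run = fk.run_hybrid(dumbbell, cfg)
        assert len(run.generations) == 1
        np.testing.assert_array_equal(run.generations[0][0].coords,
                                      dumbbell.coords)

    def test_generation_sizes_and_rmsd_bound(self, dumbbell):
        cfg = fk.HybridConfig(n_modes=4, n_generations=3,
                              confs_per_parent=6, target_rmsd=1.0,
                              max_clusters=[2, 3, 4], seed=2)
        run = fk.run_hybrid(dumbbell, cfg)
        sizes = [len(g) for g in run.generations]
        assert sizes[0] == 1
        assert all(s <= m for s, m in zip(sizes[1:], [2, 3, 4]))
        assert len(run.all_structures()) <= 1 + 2 + 3 + 4
        # every structure stays within g * target_rmsd of the start
        for g, gen in enumerate(run.generations):
            for s in gen:
                rmsd = fk.kabsch_superpose(s.coords, dumbbell.coords).rmsd
                assert rmsd <= g * 1.0 + 1e-6

    def test_bit_identical_reruns(self, dumbbell):
        cfg = fk.HybridConfig(n_modes=3, n_generations=2,
                              confs_per_parent=5, target_rmsd=1.5,
                              max_clusters=[2, 3], seed=7)
        r1 = fk.run_hybrid(dumbbell, cfg)
        r2 = fk.run_hybrid(dumbbell, cfg)
        a, b = r1.all_structures(), r2.all_structures()
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)

    def test_manifest_provenance(self, dumbbell):
        cfg = fk.HybridConfig(n_modes=3, n_generations=1,
                              confs_per_parent=4, target_rmsd=1.0,
                              max_clusters=[2], seed=3)
        run = fk.run_hybrid(dumbbell, cfg)
        assert run.provenance["seed"] == 3
        assert set(run.manifest.columns) >= {"generation", "member",
                                             "parent", "rmsd_to_parent"}
        assert (run.manifest["generation"] == 0).sum() == 1

    def test_enm_relaxer_reduces_strain(self, dumbbell, dumbbell_anm):
        """The bundled ENM relaxer pulls contact distances toward their
        rest lengths without collapsing the structure."""
        conf = fk.sample_conformers(dumbbell, dumbbell_anm, 1, 3.0, 4,
                                    np.random.default_rng(1))[0]
        relaxer = fk.analysis_sampling.make_enm_relaxer(n_steps=10)
        out = relaxer(conf, np.random.default_rng(0))
        assert out.coords.shape == conf.coords.shape
        assert np.abs(out.coords - conf.coords).max() < 5.0

    def test_mismatched_schedule_rejected(self):
        with pytest.raises(ValueError):
            fk.HybridConfig(n_generations=3, max_clusters=[5])
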