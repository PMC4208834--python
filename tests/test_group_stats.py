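"""Vertex-wise GLM, factorial contrast, and cluster permutation machinery."""

import numpy as np
import pytest
from scipy import stats

import cortsync.group_stats as gs
from cortsync.synth import build_toy_source_space


@pytest.fixture(scope="module")
def src100():
    return build_toy_source_space(100, seed=2)


class TestVertexwiseGLM:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 10)
        maps = np.outer(x, np.ones(5)) * [1, 2, -1, 3, -2]
        t, p, excl = gs.vertexwise_glm(maps + 1e-9 * np.random.default_rng(0)
                                       .standard_normal(maps.shape), x)
        assert np.all(p < 1e-8)
        assert np.all(np.sign(t) == [1, 1, -1, 1, -1])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((10, 2000))
        t, p, excl = gs.vertexwise_glm(maps, rng.standard_normal(10))
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.standard_normal(8)
        y = rng.standard_normal((8, 3))
        t, p, _ = gs.vertexwise_glm(y, x)
        for j in range(3):
            fit = sm.OLS(y[:, j], sm.add_constant(x)).fit()
            assert t[j] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert p[j] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constant_vertex_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((8, 4))
        maps[:, 2] = 5.0
        t, p, excl = gs.vertexwise_glm(maps, rng.standard_normal(8))
        assert excl[2] and p[2] == 1.0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gs.vertexwise_glm(np.zeros((6, 2)), np.ones(6))


class TestPreResponseContrast:
    def _cells(self, dmap, rng, scale=0.0):
        cells = {}
        for cond in ("incongruent", "congruent"):
            for hand in ("left", "right"):
                base = rng.standard_normal(dmap.shape) * scale
                cells[(cond, hand)] = base + (dmap if cond == "incongruent" else 0)
        return cells

    def test_constant_difference_loads_on_intercept(self):
        rng = np.random.default_rng(4)
        dmap = np.ones((8, 6)) * 0.5
        cells = {}
        for cond in ("incongruent", "congruent"):
            for hand in ("left", "right"):
                noise = 0.01 * rng.standard_normal((8, 6))
                cells[(cond, hand)] = noise + (dmap if cond == "incongruent" else 0)
        cov = rng.standard_normal(8)
        t_beh, t_main, _ = gs.pre_response_contrast(cells, cov)
        assert np.all(np.abs(t_beh) < 3)
        assert np.all(t_main > 10)

    def test_hand_relabeling_is_symmetric(self):
        rng = np.random.default_rng(5)
        cells = {(c, h): rng.standard_normal((6, 4))
                 for c in ("incongruent", "congruent")
                 for h in ("left", "right")}
        cov = rng.standard_normal(6)
        swapped = {(c, {"left": "right", "right": "left"}[h]): v
                   for (c, h), v in cells.items()}
        a = gs.pre_response_contrast(cells, cov)
        b = gs.pre_response_contrast(swapped, cov)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)

    def test_missing_cell_named(self):
        cells = {("incongruent", "left"): np.zeros((4, 2))}
        with pytest.raises(ValueError, match="congruent"):
            gs.pre_response_contrast(cells, np.arange(4))


class TestClusterComponents:
    def _flood_fill(self, mask, edges):
        """Independent oracle: BFS components of the thresholded graph."""
        from collections import deque

        adj = {}
        for a, b in edges:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        seen, comps = set(), []
        for start in np.nonzero(mask)[0]:
            if start in seen:
                continue
            comp, dq = [], deque([int(start)])
            seen.add(int(start))
            while dq:
                u = dq.popleft()
                comp.append(u)
                for w in adj.get(u, []):
                    if mask[w] and w not in seen:
                        seen.add(w)
                        dq.append(w)
            comps.append(sorted(comp))
        return sorted(comps)

    def test_matches_flood_fill_oracle_on_random_graphs(self, src100):
        from scipy import sparse

        rng = np.random.default_rng(6)
        edges = src100.edges
        adj = src100.adjacency_sparse()
        areas = src100.vertex_area
        for _ in range(30):
            mask = rng.uniform(size=src100.n_vertices) < 0.3
            got = gs._components_mass(mask, adj, areas)
            got_sets = sorted(sorted(m.tolist()) for m, _ in got)
            expect = self._flood_fill(mask, edges)
            assert got_sets == expect
            for members, mass in got:
                assert mass == pytest.approx(areas[members].sum())


class TestClusterPermutation:
    def _design(self, maps, cov, nperm=200):
        return gs.PermutationDesign(
            subject_maps=maps, covariate=cov, stat="slope",
            spec=gs.DesignSpec(n_permutations=nperm))

    def test_no_suprathreshold_no_clusters(self, src100):
        # maps constant across subjects: every vertex is excluded (p = 1),
        # so no suprathreshold vertex exists and the cluster list is empty
        rng = np.random.default_rng(7)
        maps = np.outer(np.ones(8), np.linspace(1, 2, src100.n_vertices))
        clusters = gs.cluster_permutation(
            self._design(maps, rng.standard_normal(8), 100), src100, seed=0)
        assert clusters == []

    def test_planted_patch_detected_once_and_covered(self, src100):
        rng = np.random.default_rng(8)
        cov = np.linspace(-1, 1, 10)
        # contiguous patch: a vertex and its graph neighborhood
        adj = src100.adjacency_sparse()
        patch = {5}
        for _ in range(2):
            grown = set(patch)
            for v in patch:
                grown.update(adj[v].indices.tolist())
            patch = grown
        patch = np.array(sorted(patch))
        maps = 0.3 * rng.standard_normal((10, src100.n_vertices))
        maps[:, patch] += np.outer(cov, np.ones(len(patch))) * 2.0
        clusters = gs.cluster_permutation(
            self._design(maps, cov, 200), src100, seed=1)
        spec = gs.DesignSpec(n_permutations=200)
        sig = gs.significant(clusters, spec)
        assert len(sig) == 1
        overlap = np.intersect1d(sig[0].vertex_ids, patch).size
        assert overlap >= 0.5 * len(patch)
        assert sig[0].max_value > 0

    def test_invariant_to_vertex_relabeling(self, src100):
        import dataclasses

        rng = np.random.default_rng(9)
        cov = np.linspace(-1, 1, 8)
        maps = rng.standard_normal((8, src100.n_vertices))
        perm = np.concatenate([
            rng.permutation(src100.hemi_vertices("lh")),
            rng.permutation(src100.hemi_vertices("rh"))])
        inv_perm = np.argsort(perm)
        relabeled = dataclasses.replace(
            src100,
            vertex_positions=src100.vertex_positions[perm],
            vertex_normals=src100.vertex_normals[perm],
            vertex_area=src100.vertex_area[perm],
            hemisphere=src100.hemisphere[perm],
            triangles=inv_perm[src100.triangles],
        )
        a = gs.cluster_permutation(self._design(maps, cov, 150), src100, seed=2)
        b = gs.cluster_permutation(self._design(maps[:, perm], cov, 150),
                                   relabeled, seed=2)
        pa = sorted(round(c.cluster_p, 6) for c in a)
        pb = sorted(round(c.cluster_p, 6) for c in b)
        assert pa == pb

    def test_map_length_mismatch_rejected(self, src100):
        with pytest.raises(ValueError, match="adjacency"):
            gs.cluster_permutation(
                self._design(np.zeros((6, 10)), np.arange(6.0), 100),
                src100, seed=0)


class TestClusterTable:
    def test_empty_list_gives_header_only(self):
        tab = gs.cluster_table([], "cACC-rh", "pre_stimulus")
        assert len(tab) == 0
        assert "size_mm2" in tab.columns and "cluster_p" in tab.columns

    def test_row_per_cluster_with_coverage(self, src100):
        from cortsync.synth import default_parcels

        parcels = default_parcels(src100, n_vertices=5, n_vertices_target=5)
        target = parcels[0]
        c = gs.ClusterResult(
            vertex_ids=target.vertex_ids, hemisphere="lh", size_mm2=400.0,
            max_value=-2.5, peak_vertex=int(target.vertex_ids[0]),
            cluster_p=0.01, freq=8.0)
        tab = gs.cluster_table([c, c], "cACC-rh", "pre_stimulus", src100, parcels)
        assert len(tab) == 2
        assert target.name in tab["coverage"].iloc[0]


def test_relative_log_power_removes_subject_scale():
    rng = np.random.default_rng(10)
    base = rng.uniform(0.5, 1.5, 300)
    scales = rng.uniform(0.2, 5.0, 8)
    maps = np.outer(scales, base)
    out = gs.relative_log_power(maps)
    # after per-subject centering the subject scale is gone
    np.testing.assert_allclose(out - out[0], 0.0, atol=1e-12)


def test_detection_rate_monotone_in_effect_size(src100):
    """Raising the planted effect amplitude never lowers the detection rate
    of the cluster test (three amplitude levels, 20 replicates each)."""
    rng = np.random.default_rng(11)
    adj = src100.adjacency_sparse()
    patch = {7}
    for _ in range(2):
        grown = set(patch)
        for v in patch:
            grown.update(adj[v].indices.tolist())
        patch = grown
    patch = np.array(sorted(patch))
    cov = np.linspace(-1, 1, 8)
    spec = gs.DesignSpec(n_permutations=200)
    rates = []
    for amp in (0.0, 0.8, 2.5):
        hits = 0
        for _ in range(20):
            maps = rng.standard_normal((8, src100.n_vertices))
            maps[:, patch] += amp * np.outer(cov, np.ones(len(patch)))
            design = gs.PermutationDesign(subject_maps=maps, covariate=cov,
                                          stat="slope", spec=spec)
            clusters = gs.cluster_permutation(design, src100,
                                              seed=int(rng.integers(2**31)))
            hits += any(c.cluster_p < spec.per_hemi_alpha
                        and np.intersect1d(c.vertex_ids, patch).size
                        for c in clusters)
        rates.append(hits / 20)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] >= 0.8
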