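"""AFCD, FAD, high-asymmetry clustering, map similarity, tSNR test."""

import numpy as np
import pandas as pd
import pytest

import hemicorr as hc
from conftest import brute_force_all_pairs, make_path_mesh, random_hull_mesh


def _cmap(targets, direction, kind="anatomical", scores=None):
    targets = np.asarray(targets, dtype=np.int64)
    if scores is None:
        scores = np.ones(len(targets))
    return hc.CorrespondenceMap(targets, scores, direction=direction, kind=kind)


@pytest.fixture(scope="module")
def chain():
    return make_path_mesh(10)


class TestAfcd:
    def test_fc_equal_ac_gives_zero(self, chain):
        ac = _cmap(np.arange(10), "L->R")
        fc = _cmap(np.arange(10), "L->R", kind="functional")
        out = hc.afcd(ac, fc, chain)
        np.testing.assert_allclose(out[:10], 0.0)

    def test_k_edge_displacement_on_chain(self, chain):
        k = 3
        ac = _cmap(np.arange(10), "L->R")
        fc_t = np.minimum(np.arange(10) + k, 9)
        fc = _cmap(fc_t, "L->R", kind="functional")
        out = hc.afcd(ac, fc, chain)
        np.testing.assert_allclose(out[0], float(k))  # 1 mm edges

    def test_matches_brute_force_oracle(self):
        mesh = random_hull_mesh(40, seed=11)
        n = mesh.n_vertices
        rng = np.random.default_rng(12)
        ac = _cmap(rng.integers(0, n, n), "L->R")
        fc = _cmap(rng.integers(0, n, n), "L->R", kind="functional")
        out = hc.afcd(ac, fc, mesh)
        oracle = brute_force_all_pairs(mesh)
        expect = oracle[ac.target_index, fc.target_index]
        np.testing.assert_allclose(out, expect, rtol=0, atol=1e-9)

    def test_direction_mismatch_error(self, chain):
        with pytest.raises(ValueError, match="direction mismatch"):
            hc.afcd(_cmap([0], "L->R"), _cmap([0], "R->L", kind="functional"), chain)

    def test_sentinel_propagates_nan(self, chain):
        ac = _cmap([hc.SENTINEL_INDEX, 1], "L->R")
        fc = _cmap([0, 1], "L->R", kind="functional")
        out = hc.afcd(ac, fc, chain)
        assert np.isnan(out[0]) and out[1] == 0.0


class TestFad:
    def _identity_maps(self, n):
        ac_lr = _cmap(np.arange(n), "L->R")
        ac_rl = _cmap(np.arange(n), "R->L")
        return ac_lr, ac_rl

    def test_fully_symmetric_pattern_gives_zero(self, chain):
        n = chain.n_vertices
        ac_lr, ac_rl = self._identity_maps(n)
        fc_lr = _cmap(np.arange(n), "L->R", kind="functional")
        fc_rl = _cmap(np.arange(n), "R->L", kind="functional")
        out = hc.fad(ac_lr, fc_lr, fc_rl, chain, ac_rl)
        np.testing.assert_allclose(out, 0.0)

    def test_criss_cross_zero_fad_large_afcd(self, chain):
        """Two anatomically paired seeds whose FCs are each other's
        anatomical correspondences: symmetric despite a large AFCD."""
        n = chain.n_vertices
        ac_lr, ac_rl = self._identity_maps(n)
        v, u = 1, 7  # far apart on the chain
        fc_lr_t = np.arange(n)
        fc_lr_t[v], fc_lr_t[u] = u, v  # criss-cross across hemispheres
        fc_lr = _cmap(fc_lr_t, "L->R", kind="functional")
        fc_rl = _cmap(fc_lr_t.copy(), "R->L", kind="functional")
        afcd_vals = hc.afcd(ac_lr, fc_lr, chain)
        fad_vals = hc.fad(ac_lr, fc_lr, fc_rl, chain, ac_rl)
        # hand-chained: FC_left' = ac_rl[u] = u; FC_right = fc_rl[v] = u
        assert afcd_vals[v] == pytest.approx(6.0)  # |7-1| mm on the chain
        assert fad_vals[v] == pytest.approx(0.0)
        assert fad_vals[u] == pytest.approx(0.0)

    def test_one_sided_displacement_equals_k(self, chain):
        n = chain.n_vertices
        ac_lr, ac_rl = self._identity_maps(n)
        k = 4
        fc_lr = _cmap(np.minimum(np.arange(n) + k, 9), "L->R", kind="functional")
        fc_rl = _cmap(np.arange(n), "R->L", kind="functional")
        out = hc.fad(ac_lr, fc_lr, fc_rl, chain, ac_rl)
        assert out[0] == pytest.approx(float(k))

    def test_excluded_chain_index_warns_with_sentinel(self, chain):
        n = chain.n_vertices
        ac_lr, ac_rl = self._identity_maps(n)
        fc_lr_t = np.arange(n)
        fc_lr = _cmap(fc_lr_t, "L->R", kind="functional")
        rl = np.arange(n)
        rl[3] = hc.SENTINEL_INDEX  # right vertex 3 excluded in ac_rl
        ac_rl_bad = _cmap(rl, "R->L")
        with pytest.warns(RuntimeWarning, match="excluded"):
            out = hc.fad(ac_lr, fc_lr, _cmap(np.arange(n), "R->L", kind="functional"),
                         chain, ac_rl_bad)
        assert np.isnan(out[3])


class TestHighFadClusters:
    def test_constant_below_threshold_empty(self, chain):
        out = hc.high_fad_clusters(np.full(chain.n_vertices, 50.0), chain, threshold=100.0)
        assert len(out) == 0

    def test_size_filter_keeps_large_patch_only(self):
        left, _, _ = hc.make_hemisphere_pair(n_subdiv=3, seed=20)
        fadv = np.zeros(left.n_vertices)
        d = hc.geodesic_from_sources(left, {0})
        patch_big = np.argsort(d)[:25]
        d2 = hc.geodesic_from_sources(left, {int(np.argmax(d))})
        patch_small = np.argsort(d2)[:10]
        fadv[patch_big] = 150.0
        fadv[patch_small] = 150.0
        out = hc.high_fad_clusters(fadv, left, threshold=100.0, min_vertices=20)
        assert len(out) == 1
        assert out.iloc[0]["size"] == 25

    def test_bridge_vertex_below_threshold_splits_clusters(self, chain):
        fadv = np.zeros(chain.n_vertices)
        fadv[[0, 1, 2]] = 200.0
        fadv[[4, 5, 6]] = 200.0  # vertex 3 stays below threshold
        out = hc.high_fad_clusters(fadv, chain, threshold=100.0, min_vertices=1)
        # oracle: connected components of the supra-threshold adjacency
        assert len(out) == 2
        assert sorted(out["size"]) == [3, 3]

    def test_ordering_by_descending_mean_fad(self, chain):
        fadv = np.zeros(chain.n_vertices)
        fadv[[0, 1]] = 120.0
        fadv[[5, 6]] = 300.0
        out = hc.high_fad_clusters(fadv, chain, threshold=100.0, min_vertices=1)
        assert list(out["mean_fad"]) == sorted(out["mean_fad"], reverse=True)
        assert out.iloc[0]["vertices"] == [5, 6]

    def test_permutation_equivariance(self):
        mesh = random_hull_mesh(60, seed=13)
        rng = np.random.default_rng(14)
        fadv = np.where(rng.random(mesh.n_vertices) < 0.3, 150.0, 0.0)
        out1 = hc.high_fad_clusters(fadv, mesh, threshold=100.0, min_vertices=2)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.argsort(perm)
        mesh_p = hc.SurfaceMesh(mesh.vertices[perm], inv[mesh.faces])
        out2 = hc.high_fad_clusters(fadv[perm][inv][perm], mesh_p, threshold=100.0,
                                    min_vertices=2)
        sizes1 = sorted(out1["size"]) if len(out1) else []
        sizes2 = sorted(out2["size"]) if len(out2) else []
        assert sizes1 == sizes2
        np.testing.assert_allclose(sorted(out1["mean_fad"]), sorted(out2["mean_fad"]))


class TestAverageCorrMap:
    def test_single_seed_returns_own_row(self):
        block = np.random.default_rng(0).uniform(-1, 1, (5, 7))
        np.testing.assert_array_equal(hc.average_corr_map([3], block), block[3])

    def test_cancellation(self):
        r = np.random.default_rng(1).uniform(-1, 1, 7)
        block = np.vstack([r, -r])
        np.testing.assert_allclose(hc.average_corr_map([0, 1], block), 0.0, atol=1e-15)

    def test_matches_loop_oracle(self):
        block = np.random.default_rng(2).uniform(-1, 1, (10, 6))
        seeds = [1, 3, 4, 7, 9]
        expect = np.zeros(6)
        for s in seeds:
            expect += block[s]
        expect /= len(seeds)
        np.testing.assert_allclose(hc.average_corr_map(seeds, block), expect)

    def test_empty_seed_set_error(self):
        with pytest.raises(ValueError, match="empty"):
            hc.average_corr_map([], np.zeros((3, 3)))


class TestMapSimilarity:
    def test_symmetric_structure_gives_rho_one(self):
        rng = np.random.default_rng(3)
        n = 12
        ac = _cmap(np.arange(n), "L->R")
        block = rng.uniform(-1, 1, (n, n))
        # right-seed maps identical to left-seed maps under the identity AC
        rho, mask = hc.map_similarity(ac, block, block)
        np.testing.assert_allclose(rho, 1.0, atol=1e-6)
        assert mask.all()

    def test_noise_maps_fall_below_threshold(self):
        rng = np.random.default_rng(4)
        n = 200  # targets per map; independent noise => rho near 0
        ac = _cmap(np.arange(n), "L->R")
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.standard_normal((1, n))
            b = rng.standard_normal((1, n))
            lr = np.tile(a, (n, 1))
            rl = np.tile(b, (n, 1))
            rho, mask = hc.map_similarity(ac, lr, rl)
            hits += bool(mask[0])
        assert hits / reps < 0.05

    def test_hand_built_four_vertex(self):
        ac = _cmap([1, 0, 3, 2], "L->R")
        lr = np.array(
            [[0.9, 0.1, 0.3, 0.2], [0.2, 0.8, 0.1, 0.4],
             [0.1, 0.2, 0.7, 0.3], [0.4, 0.1, 0.2, 0.6]]
        )
        rl = lr[::-1].copy()
        rho, _ = hc.map_similarity(ac, lr, rl)
        # independent hand computation for seed v = 0 (partner w = 1):
        # remapped left targets u=0..3 -> right ac[u] = [1,0,3,2]
        a = lr[0, [1, 0, 3, 2]]
        b = rl[1, :]
        expect = np.corrcoef(a, b)[0, 1]
        assert rho[0] == pytest.approx(expect, abs=1e-12)


class TestTsnr:
    def test_definition(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        data = (100.0 + 10.0 * x)[None, :]
        ts = hc.TimeSeriesSet(data)
        assert hc.tsnr(ts)[0] == pytest.approx(10.0)

    def test_identical_tsnr_no_flags(self):
        rng = np.random.default_rng(6)
        base = [rng.standard_normal((4, 30)) + 50 for _ in range(8)]
        left = [hc.TimeSeriesSet(b) for b in base]
        right = [hc.TimeSeriesSet(b.copy(), hemisphere="right") for b in base]
        ac_rl = _cmap(np.arange(4), "R->L")
        out = hc.tsnr_asymmetry(left, right, ac_rl, alpha=0.01)
        assert not out["flagged"].any()

    def test_consistent_shift_flagged_at_n10(self):
        """Left tSNR above right for every one of 10 subjects: the exact
        signed-rank two-sided p is 2/2^10 < 0.01, so the vertex flags."""
        rng = np.random.default_rng(7)
        left, right = [], []
        for s in range(10):
            x = rng.standard_normal((2, 100))
            x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            right_data = 100.0 + 10.0 * x
            left_data = 100.0 + (10.0 / (1.0 + 0.1 * (s + 1) / 10)) * x  # higher tSNR
            left.append(hc.TimeSeriesSet(left_data))
            right.append(hc.TimeSeriesSet(right_data, hemisphere="right"))
        out = hc.tsnr_asymmetry(left, right, _cmap(np.arange(2), "R->L"), alpha=0.01)
        assert out["flagged"].all()
        assert np.allclose(out["p_value"], 2.0 / 1024.0)

    def test_too_few_subjects_error(self):
        ts = [hc.TimeSeriesSet(np.random.default_rng(0).standard_normal((2, 10)))] * 3
        with pytest.raises(ValueError, match="at least 6"):
            hc.tsnr_asymmetry(ts, ts, _cmap(np.arange(2), "R->L"))


class TestSymmetryReport:
    def test_cumulative_histogram(self):
        edges, cum = hc.SymmetryReport.cumulative_histogram(np.array([0.5, 1.5, 2.5, 2.6]))
        assert cum[-1] == pytest.approx(1.0)
        assert cum[0] == pytest.approx(0.25)

    def test_summary_fields(self, chain):
        rep = hc.SymmetryReport(
            afcd_lr=np.array([0.0, 1.0, 2.0]),
            afcd_rl=np.array([0.0, 0.0, np.nan]),
            fad=np.array([0.0, 4.0, 8.0]),
            cluster_table=pd.DataFrame(),
        )
        s = rep.summarize()
        assert s["afcd_lr"]["median_mm"] == 1.0
        assert s["afcd_rl"]["n"] == 2
        assert s["fad"]["mean_mm"] == pytest.approx(4.0)
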