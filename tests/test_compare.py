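"""Similarity levels, method grouping, variance decomposition, null."""

import warnings

import numpy as np
import pytest

from multidfc import (dfc_array_from_connections, group_methods,
                      intersubject_similarity, mutual_information_metric,
                      overall_similarity, spatial_similarity,
                      temporal_similarity, time_shuffle_null,
                      variance_decomposition)
from multidfc.compare import SimilarityResult
from multidfc.errors import ParameterError, ValidationError


def conn_array(rng, s=3, m=3, t=10, r=6):
    c = r * (r - 1) // 2
    return rng.standard_normal((s, m, t, c))


def as_dfc(conn, method_ids=None, rsn_labels=None):
    s, m = conn.shape[:2]
    if method_ids is None:
        method_ids = [f"m{i}" for i in range(m)]
    return dfc_array_from_connections(
        conn, [f"sub{i}" for i in range(s)], method_ids, rsn_labels=rsn_labels
    )


class TestMutualInformation:
    def test_identical_vectors_reach_log2_bins(self, rng):
        x = rng.standard_normal(1000)
        assert mutual_information_metric(x, x, bins=10) == pytest.approx(
            np.log2(10), abs=1e-9
        )

    def test_independent_vectors_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert mutual_information_metric(x, y) < 0.02

    def test_symmetric(self, rng):
        x, y = rng.standard_normal((2, 500))
        assert mutual_information_metric(x, y) == pytest.approx(
            mutual_information_metric(y, x), abs=1e-12
        )

    def test_short_vector_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            mutual_information_metric(rng.standard_normal(30), rng.standard_normal(30))


class TestSimilarityLevels:
    def test_self_similarity_is_one_everywhere(self, rng):
        conn = conn_array(rng)
        conn[:, 1] = conn[:, 0]  # duplicate method
        arr = as_dfc(conn)
        for fn in (overall_similarity, spatial_similarity, temporal_similarity):
            for metric in ("spearman", "pearson"):
                sim = fn(arr, metric)
                np.testing.assert_allclose(np.diag(sim.matrix), 1.0, atol=1e-12)
                np.testing.assert_allclose(sim.matrix[0, 1], 1.0, atol=1e-10)
                np.testing.assert_allclose(sim.matrix, sim.matrix.T, atol=1e-12)

    def test_monotone_transform_spearman_one_pearson_below(self, rng):
        conn = conn_array(rng, m=2)
        conn[:, 1] = np.exp(conn[:, 0])  # strictly monotone transform
        arr = as_dfc(conn)
        sp = overall_similarity(arr, "spearman").matrix[0, 1]
        pe = overall_similarity(arr, "pearson").matrix[0, 1]
        assert sp == pytest.approx(1.0, abs=1e-12)
        assert pe < 1.0

    def test_independent_methods_near_zero_overall(self, rng):
        sims = []
        for _ in range(20):
            arr = as_dfc(conn_array(rng, s=1, m=2, t=38, r=12))
            sims.append(overall_similarity(arr, "spearman").matrix[0, 1])
        assert abs(np.mean(sims)) < 0.05

    def test_spatial_anticorrelated_slices(self, rng):
        conn = conn_array(rng, m=2)
        conn[:, 1] = -conn[:, 0]
        arr = as_dfc(conn)
        sim = spatial_similarity(arr, "pearson")
        assert sim.matrix[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_temporal_time_reversal_is_minus_one(self, rng):
        t = 10
        base = np.cumsum(np.abs(conn_array(rng, s=1, m=1, t=t)) + 0.1, axis=2)
        conn = np.concatenate([base, base[:, :, ::-1, :]], axis=1)
        arr = as_dfc(conn)
        sim = temporal_similarity(arr, "spearman")
        assert sim.matrix[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_spatial_temporal_dissociation(self, rng):
        """Shuffling each time slice spatially with an independent
        permutation kills temporal similarity while the value multisets of
        every slice -- hence sorted-slice spatial structure -- coincide."""
        conn = conn_array(rng, s=2, m=1, t=12, r=10)
        shuffled = conn.copy()
        c = conn.shape[-1]
        for a in range(conn.shape[0]):
            for k in range(conn.shape[2]):
                shuffled[a, 0, k] = conn[a, 0, k, rng.permutation(c)]
        arr = as_dfc(np.concatenate([conn, shuffled], axis=1))
        tmp = temporal_similarity(arr, "spearman").matrix[0, 1]
        assert abs(tmp) < 0.2
        # sorted spatial profiles agree exactly
        np.testing.assert_allclose(
            np.sort(conn[0, 0], axis=-1), np.sort(shuffled[0, 0], axis=-1)
        )

    def test_temporal_constant_connections_excluded(self, rng):
        conn = conn_array(rng, m=2)
        conn[:, :, :, 0] = 1.0  # one constant connection for every method
        arr = as_dfc(conn)
        sim = temporal_similarity(arr, "spearman")
        assert sim.info["excluded_connection_pairs"] > 0
        assert np.all(np.isfinite(sim.matrix))

    def test_intersubject_identical_methods(self, rng):
        conn = conn_array(rng, s=4, m=2)
        conn[:, 1] = conn[:, 0]
        sim = intersubject_similarity(as_dfc(conn), "spearman")
        assert sim.matrix[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_intersubject_pair_count(self, rng):
        """S subjects produce S(S-1)/2 intersubject correlations."""
        assert 395 * (395 - 1) // 2 == 77_815
        conn = conn_array(rng, s=5, m=2)
        arr = as_dfc(conn)
        iu = np.triu_indices(5, k=1)
        assert iu[0].size == 10

    def test_intersubject_needs_three_subjects(self, rng):
        with pytest.raises(ParameterError):
            intersubject_similarity(as_dfc(conn_array(rng, s=2)))


class TestGrouping:
    def _block_similarity(self, blocks=(3, 2, 2), intra=0.8, inter=0.2):
        m = sum(blocks)
        mat = np.full((m, m), inter)
        start = 0
        for b in blocks:
            mat[start: start + b, start: start + b] = intra
            start += b
        np.fill_diagonal(mat, 1.0)
        return SimilarityResult(
            "overall", "spearman", mat, [f"m{i}" for i in range(m)]
        )

    @pytest.mark.parametrize("blocks", [(3, 2, 2), (4, 2, 1), (2, 2, 3), (3, 3, 1)])
    def test_recovers_planted_blocks(self, blocks):
        sim = self._block_similarity(blocks)
        grouping = group_methods(sim)
        assert grouping.n_groups == len(blocks)
        expected, start = [], 0
        for b in blocks:
            expected.append({f"m{i}" for i in range(start, start + b)})
            start += b
        got = [set(map(str, g)) for g in grouping.groups()]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_uniform_similarity_single_group(self):
        sim = self._block_similarity((7,), intra=0.5, inter=0.5)
        assert group_methods(sim).n_groups == 1

    def test_nan_raises_with_guidance(self):
        sim = self._block_similarity()
        sim.matrix[0, 1] = sim.matrix[1, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            group_methods(sim)


class TestVarianceDecomposition:
    def test_identical_methods_zero_ratio(self, rng):
        conn = conn_array(rng, m=1)
        conn = np.repeat(conn, 3, axis=1)
        vr = variance_decomposition(as_dfc(conn))
        np.testing.assert_allclose(vr.var_method, 0.0, atol=1e-15)
        assert vr.mean_ratio_method_time == pytest.approx(0.0, abs=1e-12)

    def test_exchangeable_permutations_ratio_near_one(self):
        """When every method's time course is an independent permutation of
        one shared value multiset, variance over methods matches variance
        over time in expectation."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s, m, t, c = 2, 7, 38, 15
            base = rng.standard_normal((s, 1, t, c))
            conn = np.stack(
                [
                    np.stack(
                        [base[a, 0, rng.permutation(t)] for _ in range(m)], axis=0
                    )
                    for a in range(s)
                ],
                axis=0,
            )
            vr = variance_decomposition(as_dfc(conn, rsn_labels=["n"] * 6))
            ratios.append(vr.mean_ratio_method_time)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_single_method_raises(self, rng):
        with pytest.raises(ParameterError):
            variance_decomposition(as_dfc(conn_array(rng, m=1)))

    def test_rsn_pair_matrix_shape_and_symmetry(self, rng):
        rsn = ["a"] * 3 + ["b"] * 3
        arr = as_dfc(conn_array(rng), rsn_labels=rsn)
        vr = variance_decomposition(arr)
        assert vr.rsn_pair_ratio.shape == (2, 2)
        np.testing.assert_allclose(vr.rsn_pair_ratio, vr.rsn_pair_ratio.T)


class TestTimeShuffleNull:
    def test_identical_arrays_minimal_p(self, rng):
        conn = conn_array(rng, s=1, m=2, t=12)
        conn[:, 1] = conn[:, 0]
        out = time_shuffle_null(as_dfc(conn), n_perm=50, seed=3)
        assert out["observed"][0, 1] == pytest.approx(1.0, abs=1e-12)
        assert out["p_values"][0, 1] == pytest.approx(1.0 / 51.0)

    def test_constant_in_time_degenerate_null(self, rng):
        conn = conn_array(rng, s=1, m=2, t=1)
        conn = np.repeat(conn, 6, axis=2)
        out = time_shuffle_null(as_dfc(conn), n_perm=20, seed=4)
        np.testing.assert_allclose(
            out["null"], np.broadcast_to(out["observed"], out["null"].shape),
            atol=1e-12,
        )

    def test_seed_reproducible(self, rng):
        conn = conn_array(rng, s=1, m=2, t=8)
        arr = as_dfc(conn)
        a = time_shuffle_null(arr, n_perm=10, seed=9)
        b = time_shuffle_null(arr, n_perm=10, seed=9)
        np.testing.assert_array_equal(a["null"], b["null"])
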