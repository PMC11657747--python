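import numpy as np
import pytest
import scipy.sparse as sp

from sparsecnv.errors import InvalidArgumentError
from sparsecnv.genome import CellBinMatrix
from sparsecnv.metacell import (HIGH, INSUFFICIENT, SUFFICIENT, MetacellParams,
                                Premetacell, categorize, fragments_to_coverage,
                                greedy_merge_pass, pairwise_distance, pca_embed,
                                run_metacelling, select_merge_distance)
from sparsecnv.simulate import (SimParams, simulate_cell_counts,
                                simulate_clone_profiles)


def test_coverage_floor_arithmetic():
    # 200 fragments of 100 bp in a 1 Mb bin is 0.02x coverage
    assert fragments_to_coverage(200, read_length=100, bin_size=1_000_000) == 0.02


class TestPcaEmbed:
    def test_rank_limits_components(self, rng):
        # 3 informative directions only
        basis = rng.normal(size=(3, 40))
        X = rng.normal(size=(30, 3)) @ basis
        emb = pca_embed(X, var_frac=1.0)
        assert emb.shape[1] == 3

    def test_identical_rows_warns_single_null_component(self):
        X = np.ones((5, 10))
        with pytest.warns(UserWarning):
            emb = pca_embed(X, var_frac=0.95)
        assert emb.shape == (5, 1) and np.all(emb == 0)

    def test_variance_threshold_is_tight(self, rng):
        X = rng.normal(size=(50, 300))
        emb = pca_embed(X, var_frac=0.95)
        # eigenvalue oracle: cumulative explained variance via SVD
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False) ** 2
        frac = np.cumsum(sv) / sv.sum()
        k = emb.shape[1]
        assert frac[k - 1] >= 0.95
        assert k == 1 or frac[k - 2] < 0.95

    def test_needs_two_cells(self):
        with pytest.raises(InvalidArgumentError):
            pca_embed(np.ones((1, 10)))


class TestCategorize:
    @pytest.mark.parametrize("mean,expected", [
        (199.9, INSUFFICIENT), (200.0, SUFFICIENT),
        (1200.0, SUFFICIENT), (1200.1, HIGH),
    ])
    def test_boundaries(self, mean, expected):
        pm = Premetacell("p", ["a"], np.full(10, mean))
        categorize([pm], 200, 1200)
        assert pm.category == expected

    def test_empty_set(self):
        assert categorize([], 200, 1200) == []


def _pm(pid, counts):
    return Premetacell(pid, [pid], np.asarray(counts, dtype=float))


class TestPairwiseDistance:
    def test_identical_profiles_distance_zero(self, rng):
        c = rng.integers(50, 150, size=40).astype(float)
        d = pairwise_distance([_pm("a", c), _pm("b", c.copy())])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_profile_distance_zero(self, rng):
        c = rng.integers(50, 150, size=40).astype(float)
        d = pairwise_distance([_pm("a", c), _pm("b", 2 * c)])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_correlation(self, rng):
        pms = [_pm(f"p{i}", rng.integers(1, 200, size=30)) for i in range(4)]
        d = pairwise_distance(pms)
        from sparsecnv.metacell import _median_of_ratios_profiles
        prof = _median_of_ratios_profiles(pms)
        for i in range(4):
            for j in range(4):
                expect = 0.0 if i == j else 1 - np.corrcoef(prof[i], prof[j])[0, 1]
                assert d[i, j] == pytest.approx(max(expect, 0.0), abs=1e-12)
        assert np.allclose(d, d.T)

    def test_constant_profile_maximal_distance(self, rng):
        with pytest.warns(UserWarning):
            d = pairwise_distance([_pm("a", np.full(10, 5)),
                                   _pm("b", rng.integers(1, 9, size=10))])
        assert d[0, 1] == 2.0


class TestGreedyMergePass:
    def test_insufficient_pair_merges_with_summed_counts(self):
        a, b = _pm("a", np.full(10, 50)), _pm("b", np.full(10, 60))
        categorize([a, b], 200, 1200)
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        out, merges = greedy_merge_pass([a, b], d, threshold=0.2)
        assert len(out) == 1 and merges == [("a", "b", 0.1)]
        assert out[0].mean_reads_per_bin == pytest.approx(110.0)

    def test_sufficient_pair_never_merges(self):
        a, b = _pm("a", np.full(10, 500)), _pm("b", np.full(10, 500))
        categorize([a, b], 200, 1200)
        out, merges = greedy_merge_pass([a, b], np.zeros((2, 2)), threshold=1.0)
        assert len(out) == 2 and merges == []

    def test_high_units_never_merge(self):
        a, b = _pm("a", np.full(10, 5000)), _pm("b", np.full(10, 50))
        categorize([a, b], 200, 1200)
        out, merges = greedy_merge_pass([a, b], np.zeros((2, 2)), threshold=1.0)
        assert merges == []

    def test_hand_built_five_unit_pass(self):
        # coverage: a,b,c insufficient; d sufficient; e high
        pms = [_pm("a", np.full(4, 10)), _pm("b", np.full(4, 20)),
               _pm("c", np.full(4, 30)), _pm("d", np.full(4, 500)),
               _pm("e", np.full(4, 2000))]
        categorize(pms, 200, 1200)
        d = np.full((5, 5), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.05   # a-b closest insufficient pair
        d[2, 3] = d[3, 2] = 0.10   # c (insuff) with d (suff)
        d[0, 2] = d[2, 0] = 0.07   # a-c closer than c-d, but a merges first with b
        out, merges = greedy_merge_pass(pms, d, threshold=0.5)
        # by hand: (a,b) at 0.05 merges; (a,c) at 0.07 blocked (a used);
        # (c,d) at 0.10 merges; e untouched
        assert merges == [("a", "b", 0.05), ("c", "d", 0.10)]
        ids = sorted(pm.id for pm in out)
        assert ids == ["a", "c", "e"]


class TestSelectMergeDistance:
    def _profiles(self, n, bins, rng):
        X = rng.integers(1, 50, size=(n, bins)).astype(float)
        return X

    def test_all_sufficient_returns_smallest_quantile(self, rng):
        pms = [_pm(f"p{i}", rng.integers(400, 600, size=20)) for i in range(4)]
        params = MetacellParams()
        cell_profiles = np.zeros((4, 20))
        row_of = {f"p{i}": i for i in range(4)}
        chosen = select_merge_distance(pms, params, cell_profiles, row_of)
        d = pairwise_distance(pms)
        upper = d[np.triu_indices(4, 1)]
        qs = np.quantile(upper, np.arange(1, 11) / 10)
        assert chosen == pytest.approx(np.unique(qs)[0])

    def test_two_scale_structure_threshold_in_gap(self, toy_bins_300, rng):
        # two tight groups of insufficient units, far apart
        base1 = rng.integers(5, 15, size=300).astype(float)
        base2 = base1[::-1] * 3 + rng.integers(0, 5, size=300)
        pms = []
        for i in range(4):
            pms.append(_pm(f"a{i}", np.maximum(base1 + rng.normal(0, 0.3, 300), 0) + 1))
        for i in range(4):
            pms.append(_pm(f"b{i}", np.maximum(base2 + rng.normal(0, 0.3, 300), 0) + 1))
        params = MetacellParams()
        profiles = np.stack([pm.counts for pm in pms])
        row_of = {pm.id: i for i, pm in enumerate(pms)}
        # use the aggregated profiles themselves as the member profiles
        for pm in pms:
            pm.members = [pm.id]
        chosen = select_merge_distance(pms, params, profiles, row_of)
        d = pairwise_distance(pms)
        between = min(d[i, j] for i in range(4) for j in range(4, 8))
        # the chosen threshold never bridges the two groups, and merging at
        # it collapses each group without mixing them
        assert chosen < between
        from sparsecnv.metacell import _merge_to_convergence
        final, _ = _merge_to_convergence(pms, chosen, params)
        for pm in final:
            groups = {m[0] for m in pm.members}
            assert len(groups) == 1

    def test_single_pair_returns_that_distance(self, rng):
        pms = [_pm("a", rng.integers(1, 50, size=20)),
               _pm("b", rng.integers(1, 50, size=20))]
        chosen = select_merge_distance(pms, MetacellParams(), np.zeros((2, 20)),
                                       {"a": 0, "b": 1})
        assert chosen == pytest.approx(pairwise_distance(pms)[0, 1])


class TestRunMetacelling:
    def _simulate(self, bins, seed, mean_reads_per_bin=15, n_cells=200):
        clones = simulate_clone_profiles(
            bins, 2, n_events=4, event_size_bins=(15, 40), seed=seed,
            cn_choices=(0, 1, 3, 4), cn_weights=(0.2, 0.3, 0.3, 0.2))
        params = SimParams(n_cells=n_cells, fractions=(0.5, 0.5),
                           mean_fragments=mean_reads_per_bin * bins.n_bins,
                           seed=seed + 50)
        return clones, *simulate_cell_counts(clones, bins, params)

    def test_planted_two_clone_purity_and_conservation(self, toy_bins_300):
        clones, matrix, labels = self._simulate(toy_bins_300, seed=2)
        res = run_metacelling(matrix, MetacellParams(seed=2))
        lab_of = {b: labels[i] for i, b in enumerate(matrix.barcodes)}
        for pm in res.metacells:
            assert len({lab_of[b] for b in pm.members}) == 1  # clone-pure
        assert sum(pm.counts.sum() for pm in res.metacells) == matrix.counts.sum()
        # assignment is a partition of the input cells
        assert sorted(res.assignment) == sorted(matrix.barcodes)

    def test_all_cells_above_cap_stay_singleton_high(self, toy_bins_300, rng):
        counts = rng.poisson(1500, size=(12, 300)).astype(np.int64)
        m = CellBinMatrix([f"c{i}" for i in range(12)], toy_bins_300,
                          sp.csr_matrix(counts))
        res = run_metacelling(m, MetacellParams(seed=0))
        assert len(res.metacells) == 12
        assert all(pm.category == HIGH for pm in res.metacells)
        assert res.merge_log == []

    def test_single_cell_single_metacell(self, toy_bins_300):
        m = CellBinMatrix(["only"], toy_bins_300,
                          sp.csr_matrix(np.ones((1, 300), dtype=np.int64)))
        res = run_metacelling(m)
        assert res.assignment == {"only": res.metacells[0].id}


def test_high_units_survive_unchanged_through_merging(toy_bins_300, rng):
    counts = np.vstack([
        rng.poisson(2000, size=(2, 300)),   # high
        rng.poisson(20, size=(6, 300)),     # insufficient
    ]).astype(np.int64)
    m = CellBinMatrix([f"c{i}" for i in range(8)], toy_bins_300,
                      sp.csr_matrix(counts))
    res = run_metacelling(m, MetacellParams(seed=1))
    high = [pm for pm in res.metacells if pm.category == HIGH]
    assert all(len(pm.members) == 1 for pm in high)
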