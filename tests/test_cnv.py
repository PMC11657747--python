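import itertools

import numpy as np
import pytest

from sparsecnv.cnv import (GAIN, LOSS, NEUTRAL, call_cnv, cluster_units,
                           collapse_deletions, correlate_to_bulk,
                           normalize_profile, CNVCalls, PARAM_TABLE)
from sparsecnv.errors import ConfigurationError, InvalidArgumentError
from sparsecnv.hmm import HMMConfig, hmm_segment
from sparsecnv.simulate import (SimParams, simulate_cell_counts,
                                simulate_clone_profiles)


def brute_force_viterbi(profile, config, sd):
    """Independent oracle: score every state path explicitly (vectorized
    enumeration; use only for short profiles)."""
    n_bins = len(profile)
    S = config.n_states
    means = config.state_means
    T = np.log(config.transition_matrix())
    paths = np.array(list(itertools.product(range(S), repeat=n_bins)), dtype=np.int8)
    ll = (-0.5 * ((profile[None, :] - means[paths]) / sd) ** 2
          - np.log(sd) - 0.5 * np.log(2 * np.pi)).sum(axis=1)
    ll += T[paths[:, :-1], paths[:, 1:]].sum(axis=1) - np.log(S)
    return paths[np.argmax(ll)]


class TestNormalize:
    def test_constant_counts_zero_ratio(self):
        out = normalize_profile(np.full(20, 100))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_doubled_bin_ratio_near_one(self):
        c = np.full(100, 10_000)
        c[3] = 20_000 + 10_000 // 100 * 2  # compensate the shifted mean
        out = normalize_profile(c)
        assert out[3] == pytest.approx(1.0, abs=0.01)

    def test_matches_direct_formula(self, rng):
        c = rng.integers(0, 50, size=30)
        out = normalize_profile(c)
        expect = np.log2((c + 0.5) / (c.mean() + 0.5))
        assert np.allclose(out, expect, atol=1e-12)

    def test_mask_excluded_from_mean_and_nan(self, rng):
        c = rng.integers(1, 50, size=10)
        mask = np.zeros(10, bool)
        mask[:3] = True
        out = normalize_profile(c, mask)
        assert np.all(np.isnan(out[:3]))
        expect = np.log2((c[3:] + 0.5) / (c[3:].mean() + 0.5))
        assert np.allclose(out[3:], expect, atol=1e-12)

    def test_all_masked_rejected(self):
        with pytest.raises(InvalidArgumentError):
            normalize_profile(np.ones(4), np.ones(4, bool))


class TestCollapse:
    def test_rule_table(self):
        out = collapse_deletions(np.array([0, 1, 2, 3, 5]))
        assert list(out) == [LOSS, LOSS, NEUTRAL, GAIN, GAIN]

    def test_all_neutral(self):
        assert np.all(collapse_deletions(np.full(7, 2)) == NEUTRAL)

    def test_random_vector_elementwise(self, rng):
        s = rng.integers(0, 6, size=100)
        out = collapse_deletions(s)
        for si, oi in zip(s, out):
            assert oi == (LOSS if si < 2 else NEUTRAL if si == 2 else GAIN)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            collapse_deletions(np.array([7]))


class TestHmmSegment:
    def test_flat_profile_all_neutral(self):
        states = hmm_segment(np.zeros(40), np.zeros(40, int), HMMConfig(e=0.995))
        assert np.all(states == 2)

    def test_step_profile_switches_at_boundary(self):
        prof = np.array([0.0] * 6 + [-1.0] * 6)
        cfg = HMMConfig(e=0.995, strength=1e30, fixed_sd=0.1)
        states = hmm_segment(prof, np.zeros(12, int), cfg)
        assert list(states) == [2] * 6 + [1] * 6

    def test_near_one_stay_probability_freezes_path(self):
        # with e = 1 - 1e-15 and the SD estimated by EM, the stay prior
        # overwhelms a 6-bin excursion of unit magnitude
        prof = np.array([0.0] * 6 + [-1.0] * 6)
        cfg = HMMConfig(e=1 - 1e-15, strength=1e30)
        states = hmm_segment(prof, np.zeros(12, int), cfg)
        assert len(set(states)) == 1

    def test_matches_brute_force_enumeration(self, rng):
        cfg = HMMConfig(e=0.9, strength=1e30, fixed_sd=0.25)
        for trial in range(5):
            prof = np.round(rng.normal(0, 0.7, size=7), 3)
            ours = hmm_segment(prof, np.zeros(7, int), cfg)
            oracle = brute_force_viterbi(prof, cfg, 0.25)
            assert np.array_equal(ours, oracle), f"trial {trial}"

    def test_no_transitions_across_chromosomes(self):
        prof = np.array([0.0, 0.0, -1.0, -1.0])
        chrom = np.array([0, 0, 1, 1])
        cfg = HMMConfig(e=1 - 1e-15, strength=1e30, fixed_sd=0.1)
        states = hmm_segment(prof, chrom, cfg)
        # each chromosome decodes to its own single state
        assert list(states) == [2, 2, 1, 1]

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hmm_segment(np.array([0.0, np.nan, 0.0]), np.zeros(3, int),
                        HMMConfig())

    def test_invalid_stay_probability(self):
        with pytest.raises(InvalidArgumentError):
            HMMConfig(e=1.5)


class TestCallCnv:
    def test_parameter_table_provenance(self, toy_bins_300, rng):
        counts = rng.poisson(100, size=(2, 300))
        calls = call_cnv(counts, toy_bins_300, ["a", "b"])
        assert calls.params["e"] == 0.995
        fine_e, fine_strength = PARAM_TABLE[100_000]
        assert fine_e == 0.999999999999999 and fine_strength == 1e30

    def test_unknown_bin_size_needs_overrides(self, rng):
        from sparsecnv.genome import ChromSizes, make_bins
        bins = make_bins(ChromSizes((("c1", 700),)), 7)
        counts = rng.poisson(100, size=(1, bins.n_bins))
        with pytest.raises(ConfigurationError):
            call_cnv(counts, bins, ["a"])
        calls = call_cnv(counts, bins, ["a"], hmm_overrides={"e": 0.99})
        assert calls.params["e"] == 0.99

    def test_planted_states_recovered_at_metacell_coverage(self, toy_bins_1000):
        accs = []
        for seed in range(3):
            clones = simulate_clone_profiles(toy_bins_1000, 2, n_events=5,
                                             event_size_bins=(20, 60), seed=seed)
            params = SimParams(n_cells=4, fractions=(0.5, 0.5),
                               mean_fragments=200 * 1000, seed=seed + 100)
            m, labels = simulate_cell_counts(clones, toy_bins_1000, params)
            calls = call_cnv(m.counts, toy_bins_1000, m.barcodes)
            for i, l in enumerate(labels):
                truth = clones[l].collapsed()
                ok = ~calls.mask
                accs.append(np.mean(calls.collapsed[i][ok] == truth[ok]))
        assert np.mean(accs) >= 0.95

    def test_collapse_invariant_to_depth_rescaling(self, toy_bins_1000):
        clones = simulate_clone_profiles(toy_bins_1000, 1, n_events=5,
                                         event_size_bins=(20, 60), seed=4)
        params = SimParams(n_cells=1, fractions=(1.0,),
                           mean_fragments=200 * 1000, seed=9)
        m, _ = simulate_cell_counts(clones, toy_bins_1000, params)
        counts = np.asarray(m.counts.todense())
        c1 = call_cnv(counts, toy_bins_1000, ["u"])
        c2 = call_cnv(counts * 16, toy_bins_1000, ["u"])
        ok = ~(c1.mask | c2.mask)
        assert np.mean(c1.collapsed[0][ok] == c2.collapsed[0][ok]) > 0.99


class TestCorrelateToBulk:
    def _calls(self, states, bins):
        states = np.atleast_2d(states).astype(np.int8)
        return CNVCalls(units=[f"u{i}" for i in range(states.shape[0])],
                        states=states, collapsed=collapse_deletions(states),
                        mask=np.zeros(states.shape[1], bool), bins=bins)

    def test_identity_assignment(self, toy_bins_300, rng):
        a = rng.integers(0, 6, 300)
        b = rng.integers(0, 6, 300)
        calls = self._calls(a, toy_bins_300)
        r, ident = correlate_to_bulk(calls, {"A": a, "B": b})
        assert r[0, 0] == pytest.approx(1.0)
        assert ident == ["A"]

    def test_zero_variance_unit_flagged(self, toy_bins_300, rng):
        calls = self._calls(np.full(300, 2), toy_bins_300)
        r, ident = correlate_to_bulk(calls, {"A": rng.integers(0, 6, 300)})
        assert np.isnan(r[0, 0]) and ident == [None]

    def test_planted_units_all_assigned_correctly(self, toy_bins_300, rng):
        bulk_a = rng.integers(0, 6, 300)
        bulk_b = rng.integers(0, 6, 300)
        units, truth = [], []
        for i in range(10):
            src = bulk_a if i % 2 == 0 else bulk_b
            noisy = src.copy()
            flip = rng.choice(300, size=30, replace=False)
            noisy[flip] = rng.integers(0, 6, 30)
            units.append(noisy)
            truth.append("A" if i % 2 == 0 else "B")
        calls = self._calls(np.stack(units), toy_bins_300)
        _, ident = correlate_to_bulk(calls, {"A": bulk_a, "B": bulk_b})
        assert ident == truth


class TestClusterUnits:
    def _calls(self, states, bins):
        states = np.asarray(states, dtype=np.int8)
        return CNVCalls(units=[f"u{i}" for i in range(states.shape[0])],
                        states=states, collapsed=collapse_deletions(states),
                        mask=np.zeros(states.shape[1], bool), bins=bins)

    def test_two_blocks_kmeans_perfect_split(self, toy_bins_300, rng):
        a = rng.integers(0, 6, 300)
        b = rng.integers(0, 6, 300)
        states = np.stack([a] * 6 + [b] * 4)
        calls = self._calls(states, toy_bins_300)
        res = cluster_units(calls, method="kmeans", param=2, seed=0)
        assert len(set(res.labels[:6])) == 1 and len(set(res.labels[6:])) == 1
        assert res.labels[0] != res.labels[6]
        assert res.labels[0] == 0  # largest cluster labelled 0

    def test_duplicated_unit_single_effective_cluster(self, toy_bins_300, rng):
        states = np.tile(rng.integers(0, 6, 300), (5, 1))
        calls = self._calls(states, toy_bins_300)
        res = cluster_units(calls, method="kmeans", param=2, seed=0)
        # k-means inertia 0: all points coincide, split is degenerate
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            states.astype(float))
        assert km.inertia_ == pytest.approx(0.0)

    def test_k_exceeding_units_rejected(self, toy_bins_300, rng):
        calls = self._calls(rng.integers(0, 6, (3, 300)), toy_bins_300)
        with pytest.raises(InvalidArgumentError):
            cluster_units(calls, method="kmeans", param=5)

    def test_leiden_deterministic_given_seed(self, toy_bins_300, rng):
        states = rng.integers(0, 6, (40, 300))
        calls = self._calls(states, toy_bins_300)
        r1 = cluster_units(calls, method="leiden", param=0.15, seed=11)
        r2 = cluster_units(calls, method="leiden", param=0.15, seed=11)
        assert np.array_equal(r1.labels, r2.labels)
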