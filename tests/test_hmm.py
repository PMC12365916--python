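"""Diplotype HMM: transitions, emissions, posteriors, crossovers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dohaplo as dh
from dohaplo import hmm
from dohaplo.impute import sequencing_emissions

from conftest import truth_alleleprobs


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        T = dh.transition_matrix(0.0, 41)
        assert np.allclose(T, np.eye(36), atol=1e-12)

    def test_long_distance_reaches_stationarity(self):
        """Rows converge to the two-independent-homolog stationary law."""
        F = 8
        stationary = np.empty(36)
        for s, (i, j) in enumerate(hmm.state_pairs(F)):
            stationary[s] = (1 if i == j else 2) / F ** 2
        # brute-force enumeration over ordered homolog pairs
        P = np.full((F, F), 1.0 / F)
        enum = np.empty(36)
        for s, (c, d) in enumerate(hmm.state_pairs(F)):
            if c == d:
                enum[s] = P[0, c] * P[0, c]
            else:
                enum[s] = 2 * P[0, c] * P[0, d]
        assert np.allclose(stationary, enum)
        T = dh.transition_matrix(1e6, 41)
        assert np.allclose(T, np.tile(stationary, (36, 1)), atol=1e-9)

    @given(st.floats(0.0, 50.0), st.integers(1, 60))
    @settings(max_examples=25, deadline=None)
    def test_rows_are_stochastic(self, d, n_gen):
        T = dh.transition_matrix(d, n_gen)
        assert np.all(T >= 0)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dh.transition_matrix(-1.0, 41)
        with pytest.raises(ValueError):
            dh.transition_matrix(1.0, 0)


class TestEmissionProbs:
    def test_flat_gl_triple_uniform_over_states(self):
        e = dh.emission_probs(np.zeros(3), np.array([0, 1] * 4),
                              "sequencing")
        assert np.allclose(e, 1.0)

    def test_noiseless_array_call_supports_matching_dose_only(self):
        row = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        e = dh.emission_probs(2, row, "array", error=0.0)
        doses = hmm.state_doses(row)
        assert np.all(e[doses == 2] == 1.0)
        assert np.all(e[doses != 2] == 0.0)

    def test_gl_ratio_matches_binomial_oracle(self):
        from scipy.stats import binom
        err = 0.01
        gl = dh.genotype_likelihoods(
            dh.AlleleDepthMatrix(ref=np.array([[10]]), alt=np.array([[0]]),
                                 nominal_coverage=1.0), err)[0, 0]
        row = np.array([0, 1, 0, 0, 0, 0, 0, 0])
        e = dh.emission_probs(gl, row, "sequencing")
        doses = hmm.state_doses(row)
        ratio = e[doses == 0][0] / e[doses == 2][0]
        oracle = binom.pmf(0, 10, err) / binom.pmf(0, 10, 1 - err)
        assert ratio == pytest.approx(oracle, rel=1e-9)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown emission model"):
            dh.emission_probs(0, np.zeros(8), "chip")


def brute_force_posteriors(emissions, cm, n_gen, n_founders):
    """Path-sum enumeration over all state sequences."""
    K = hmm.n_states(n_founders)
    M = emissions.shape[0]
    Ts = [dh.transition_matrix(d, n_gen, n_founders)
          for d in np.diff(cm)]
    post = np.zeros((M, K))
    for path in itertools.product(range(K), repeat=M):
        w = emissions[0, path[0]] / K
        for m in range(1, M):
            w *= Ts[m - 1][path[m - 1], path[m]] * emissions[m, path[m]]
        for m, s in enumerate(path):
            post[m, s] += w
    return post / post.sum(axis=1, keepdims=True)


class TestDiplotypePosteriors:
    def test_single_marker_flat_emissions_uniform(self):
        post = dh.diplotype_posteriors(np.ones((1, 36)), [0.0], 41)
        assert np.allclose(post, 1 / 36)

    @pytest.mark.parametrize("n_founders, M, seed", [
        (2, 3, 0), (2, 4, 1), (3, 3, 2),
    ])
    def test_matches_path_enumeration(self, n_founders, M, seed):
        rng = np.random.default_rng(seed)
        K = hmm.n_states(n_founders)
        emissions = rng.uniform(0.05, 1.0, size=(M, K))
        cm = np.cumsum(rng.uniform(0.0, 2.0, size=M))
        want = brute_force_posteriors(emissions, cm, 20, n_founders)
        got = dh.diplotype_posteriors(emissions, cm, 20,
                                      n_founders=n_founders,
                                      engine="dense")
        assert np.allclose(got, want, atol=1e-10)

    def test_factored_engine_equals_dense(self):
        rng = np.random.default_rng(3)
        emissions = rng.uniform(0.01, 1.0, size=(2, 30, 36))
        cm = np.cumsum(rng.uniform(0.0, 0.5, size=30))
        dense = dh.diplotype_posteriors(emissions, cm, 41, engine="dense")
        fact = dh.diplotype_posteriors(emissions, cm, 41,
                                       engine="factored")
        assert np.allclose(dense, fact, atol=1e-10)

    def test_posterior_rows_normalized(self, small_panel, cohort):
        mos, depths = cohort
        gl = dh.genotype_likelihoods(depths)
        post = dh.diplotype_posteriors(
            sequencing_emissions(gl, small_panel), small_panel.cm, 41)
        assert np.allclose(post.sum(axis=-1), 1.0, atol=1e-9)

    def test_non_finite_emissions_rejected(self):
        e = np.ones((2, 36))
        e[1, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            dh.diplotype_posteriors(e, [0.0, 1.0], 41)

    def test_high_depth_recovers_true_state(self):
        panel = dh.simulate_founder_panel(2000, 20_000_000, seed=51)
        mos = dh.simulate_do_diplotypes(panel, 41, 1, seed=52)[0]
        ref, alt = dh.simulate_reads(mos, panel, 30.0, base_error=0.001,
                                     seed=53)
        depths = dh.AlleleDepthMatrix(ref=ref[None], alt=alt[None],
                                      nominal_coverage=30.0)
        gl = dh.genotype_likelihoods(depths)
        post = dh.diplotype_posteriors(
            sequencing_emissions(gl, panel), panel.cm, 41)[0]
        fnd = mos.founders_at(panel.positions)
        true_state = np.array([
            hmm.state_index(a, b) for a, b in fnd])
        # away from junctions: drop markers within 250 kb of any breakpoint
        bps = [b for h in mos.junctions() for b in h]
        away = np.ones(panel.n_markers, dtype=bool)
        for b in bps:
            away &= np.abs(panel.positions - b) > 250_000
        frac = np.mean(post[away, true_state[away]] >= 0.999)
        assert frac >= 0.99


class TestAlleleCondensation:
    def test_fixed_homozygote(self):
        probs = np.zeros(36)
        probs[hmm.state_index(0, 0)] = 1.0
        assert dh.genoprob_to_alleleprob(probs)[0] == 1.0

    def test_heterozygote_splits_half_half(self):
        probs = np.zeros(36)
        probs[hmm.state_index(0, 1)] = 1.0
        a = dh.genoprob_to_alleleprob(probs)
        assert a[0] == 0.5 and a[1] == 0.5

    def test_uniform_row_gives_one_eighth(self):
        a = dh.genoprob_to_alleleprob(np.full(36, 1 / 36))
        assert np.allclose(a, 0.125)

    def test_conserves_total_probability(self):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet(np.ones(36), size=(3, 50))
        a = dh.genoprob_to_alleleprob(probs)
        assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-12)


class TestMaxmargPath:
    def test_uniform_row_uncertain(self):
        assert dh.maxmarg_path(np.full((1, 36), 1 / 36))[0] == -1

    def test_point_mass_rows_called(self):
        probs = np.zeros((3, 36))
        for m, s in enumerate((4, 4, 30)):
            probs[m, s] = 1.0
        assert list(dh.maxmarg_path(probs)) == [4, 4, 30]

    def test_threshold_boundary(self):
        row = np.full(36, 0.06 / 35)
        row[10] = 0.94
        assert dh.maxmarg_path(row[None], minprob=0.95)[0] == -1
        assert dh.maxmarg_path(row[None], minprob=0.90)[0] == 10


class TestLocateCrossovers:
    def test_constant_path_no_crossovers(self):
        path = np.full(10, hmm.state_index(2, 5))
        pos = np.arange(10) * 1000 + 1
        xo = dh.locate_crossovers(path, pos)
        assert xo.total == 0
        assert xo.block_lengths == [pos[-1] - pos[0]]

    def test_single_homolog_change_is_one_crossover(self):
        path = np.array([hmm.state_index(0, 0), hmm.state_index(0, 1)])
        xo = dh.locate_crossovers(path, [100, 200])
        assert xo.total == 1
        assert xo.boundaries == [(100, 200, 1)]

    def test_disjoint_pairs_count_two(self):
        # verified against exhaustive founder-multiset difference
        def oracle(a, b):
            from collections import Counter
            ca, cb = Counter(a), Counter(b)
            return 2 - sum((ca & cb).values())

        pairs = hmm.state_pairs(8)
        rng = np.random.default_rng(1)
        for _ in range(50):
            s0, s1 = rng.integers(0, 36, size=2)
            path = np.array([s0, s1])
            xo = dh.locate_crossovers(path, [100, 200])
            assert xo.total == oracle(pairs[s0], pairs[s1])

    def test_missing_calls_bridged(self):
        path = np.array([hmm.state_index(0, 1), -1, -1,
                         hmm.state_index(1, 2)])
        xo = dh.locate_crossovers(path, [10, 20, 30, 40])
        assert xo.boundaries == [(10, 40, 1)]

    def test_block_lengths_sum_to_span(self):
        rng = np.random.default_rng(5)
        path = rng.integers(0, 36, size=20)
        pos = np.sort(rng.choice(100_000, 20, replace=False))
        xo = dh.locate_crossovers(path, pos)
        assert sum(xo.block_lengths) == pytest.approx(pos[-1] - pos[0])

    def test_dense_error_free_counts_equal_truth(self):
        """Dense enough that every short block carries markers able to
        break identity-by-state with the neighbouring founders."""
        panel = dh.simulate_founder_panel(10_000, 30_000_000, seed=61)
        mos = dh.simulate_do_diplotypes(panel, 41, 4, seed=62)
        calls = dh.simulate_array_calls(mos, panel,
                                        np.arange(panel.n_markers),
                                        call_error=0.0, seed=63)
        from dohaplo.impute import array_emissions
        post = dh.diplotype_posteriors(
            array_emissions(calls, panel, 1e-6), panel.cm, 41)
        for i, m in enumerate(mos):
            path = dh.maxmarg_path(post[i])
            xo = dh.locate_crossovers(path, panel.positions)
            assert xo.total == m.observable_junction_count()

    def test_truth_recovery_at_1x(self, small_panel):
        panel = dh.simulate_founder_panel(2000, 50_000_000, seed=71)
        mos = dh.simulate_do_diplotypes(panel, 41, 10, seed=72)
        depths = dh.simulate_read_cohort(mos, panel, 1.0, seed=73)
        gl = dh.genotype_likelihoods(depths)
        post = dh.diplotype_posteriors(
            sequencing_emissions(gl, panel), panel.cm, 41)
        probs = dh.genoprob_to_alleleprob(post)
        hits = []
        for i, m in enumerate(mos):
            truth = truth_alleleprobs(m, panel) > 0
            top = np.argmax(probs[i], axis=1)
            hits.append(truth[np.arange(panel.n_markers), top])
        assert np.mean(np.concatenate(hits)) >= 0.95
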