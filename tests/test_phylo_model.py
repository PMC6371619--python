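"""TN93 kernel, pruning likelihood, coalescent prior, clock draws."""

from itertools import product

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import matrix_for, three_leaf_tree, two_leaf_tree
from phyloallele.phylo_model import (
    ClockModel,
    CoalescentParams,
    TN93Params,
    coalescent_log_prior,
    draw_branch_rates,
    effective_branch_lengths,
    encode_leaf_states,
    tn93_rate_matrix,
    tn93_transition_probs,
    tree_log_likelihood,
    transition_matrices,
)
from phyloallele.simulate import simulate_coalescent_tree


def random_params(rng):
    return TN93Params(
        pi=rng.dirichlet([5.0] * 4),
        kappa1=float(rng.uniform(0.5, 6)),
        kappa2=float(rng.uniform(0.5, 6)),
    )


class TestTN93Params:
    def test_frequencies_must_be_positive_and_normalized(self):
        with pytest.raises(ValueError):
            TN93Params(pi=np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError):
            TN93Params(pi=np.array([0.4, 0.4, 0.4, 0.4]))
        with pytest.raises(ValueError):
            TN93Params(kappa1=-1.0)

    def test_generator_is_normalized_to_one_substitution(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        Q = tn93_rate_matrix(p)
        assert np.isclose(-np.dot(p.pi, np.diag(Q)), 1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        p = TN93Params()
        assert np.allclose(tn93_transition_probs(p, 0.0), np.eye(4),
                           atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        rng = np.random.default_rng(2)
        p = random_params(rng)
        P = tn93_transition_probs(p, 1e4)
        assert np.allclose(P, np.tile(p.pi, (4, 1)), atol=1e-8)

    def test_rows_sum_to_one_and_reversibility(self):
        rng = np.random.default_rng(3)
        p = random_params(rng)
        for t in [0.0, 0.01, 0.1, 1.0, 10.0]:
            P = tn93_transition_probs(p, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            flux = p.pi[:, None] * P
            assert np.allclose(flux, flux.T, atol=1e-10)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(4)
        p = random_params(rng)
        for s, t in [(0.05, 0.2), (0.5, 1.5)]:
            lhs = tn93_transition_probs(p, s) @ tn93_transition_probs(p, t)
            assert np.allclose(lhs, tn93_transition_probs(p, s + t),
                               atol=1e-12)

    def test_reduces_to_jc69_closed_form(self):
        p = TN93Params(kappa1=1.0, kappa2=1.0)
        for t in [0.01, 0.3, 2.0]:
            P = tn93_transition_probs(p, t)
            same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
            expect = np.full((4, 4), diff)
            np.fill_diagonal(expect, same)
            assert np.allclose(P, expect, atol=1e-12)

    def test_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            p = random_params(rng)
            Q = tn93_rate_matrix(p)
            for t in [0.02, 0.7, 4.0]:
                assert np.allclose(
                    tn93_transition_probs(p, t), expm(Q * t), atol=1e-10
                )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tn93_transition_probs(TN93Params(), -0.1)


def brute_force_log_likelihood(tree, clock, params, matrix):
    """Exhaustive sum over all internal-node state assignments, per site."""
    ls = encode_leaf_states(matrix, tree.taxa)
    P = transition_matrices(params, effective_branch_lengths(tree, clock))
    internals = [v for v in range(tree.n_nodes) if tree.children[v, 0] >= 0]
    total = 0.0
    for s in range(ls.shape[1]):
        site = 0.0
        for assign in product(range(4), repeat=len(internals)):
            st = dict(zip(internals, assign))
            st.update({leaf: ls[leaf, s] for leaf in range(tree.n_leaves)})
            pr = params.pi[st[tree.root]]
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p >= 0:
                    pr *= P[v][st[p], st[v]]
            site += pr
        total += np.log(site)
    return total


class TestTreeLogLikelihood:
    def test_two_identical_leaves_zero_branches(self):
        tree = two_leaf_tree(1e-13)
        params = TN93Params(pi=np.array([0.4, 0.2, 0.2, 0.2]))
        m = matrix_for(tree, ["A", "A"])
        ll = tree_log_likelihood(tree, ClockModel(), params, m)
        assert np.isclose(ll, np.log(0.4), atol=1e-9)

    def test_pruning_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        clock = ClockModel()
        for n in [2, 3, 4, 5]:
            for _ in range(3):
                tree = simulate_coalescent_tree(n, 1.0, rng)
                params = random_params(rng)
                k = int(rng.integers(1, 4))
                states = [
                    "".join(rng.choice(list("ACGT"), k)) for _ in range(n)
                ]
                m = matrix_for(tree, states)
                a = tree_log_likelihood(tree, clock, params, m)
                b = brute_force_log_likelihood(tree, clock, params, m)
                assert abs(a - b) < 1e-10

    def test_duplicated_site_doubles_contribution(self):
        rng = np.random.default_rng(12)
        tree = simulate_coalescent_tree(4, 1.0, rng)
        params = random_params(rng)
        m1 = matrix_for(tree, ["A", "C", "G", "A"])
        m2 = matrix_for(tree, ["AA", "CC", "GG", "AA"])
        ll1 = tree_log_likelihood(tree, ClockModel(), params, m1)
        ll2 = tree_log_likelihood(tree, ClockModel(), params, m2)
        assert np.isclose(ll2, 2 * ll1, atol=1e-10)

    def test_invariant_under_leaf_reordering(self):
        rng = np.random.default_rng(13)
        tree = simulate_coalescent_tree(5, 1.0, rng)
        params = random_params(rng)
        states = ["ACT", "ACA", "GCA", "ATA", "ACT"]
        m1 = matrix_for(tree, states)
        perm = [3, 0, 4, 1, 2]
        from phyloallele.variant_matrix import VariantMatrix

        m2 = VariantMatrix(
            names=[tree.taxa[i] for i in perm],
            states=[states[i] for i in perm],
            site_positions=[1, 2, 3],
            reference_name=tree.taxa[perm[0]],
        )
        assert np.isclose(
            tree_log_likelihood(tree, ClockModel(), params, m1),
            tree_log_likelihood(tree, ClockModel(), params, m2),
            atol=1e-12,
        )

    def test_taxa_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        tree = simulate_coalescent_tree(3, 1.0, rng)
        m = matrix_for(["x", "y", "z"], ["A", "C", "G"])
        with pytest.raises(ValueError, match="taxa"):
            tree_log_likelihood(tree, ClockModel(), TN93Params(), m)

    def test_ascertainment_conditions_on_variability(self):
        rng = np.random.default_rng(15)
        tree = simulate_coalescent_tree(3, 1.0, rng)
        params = random_params(rng)
        clock = ClockModel()
        m = matrix_for(tree, ["AC", "CC", "CA"])
        plain = tree_log_likelihood(tree, clock, params, m)
        asc = tree_log_likelihood(tree, clock, params, m,
                                  ascertainment=True)
        # brute-force P(constant site)
        p_const = 0.0
        for x in "ACGT":
            mm = matrix_for(tree, [x, x, x])
            p_const += np.exp(
                tree_log_likelihood(tree, clock, params, mm)
            )
        assert np.isclose(asc, plain - 2 * np.log1p(-p_const), atol=1e-9)
        assert asc > plain  # conditioning on a subset raises the density

    def test_invariant_counts_reproduce_full_alignment_likelihood(self):
        """Variant-column likelihood plus per-base invariant counts must
        equal pruning on the reconstructed full alignment."""
        from phyloallele.simulate import SimulationConfig, simulate_dataset
        from phyloallele.variant_matrix import (
            VariantMatrix,
            extract_variant_sites,
        )

        rng = np.random.default_rng(16)
        truth = simulate_dataset(SimulationConfig(
            n_alleles=6, seq_length=80, mutation_rate=0.02,
            seed=int(rng.integers(1, 2**31)),
        ))
        aln = truth.leaf_alleles
        m = extract_variant_sites(aln, reference_name=aln.names[0])
        full = VariantMatrix(
            names=list(aln.names), states=list(aln.sequences),
            site_positions=list(range(1, aln.alignment_length + 1)),
            reference_name=aln.names[0],
        )
        params = random_params(rng)
        clock = ClockModel(mean_rate=0.02)
        ll_full = tree_log_likelihood(truth.tree, clock, params, full)
        ll_split = tree_log_likelihood(
            truth.tree, clock, params, m,
            invariant_counts=m.invariant_base_counts,
        )
        assert np.isclose(ll_full, ll_split, atol=1e-8)

    def test_ascertainment_and_invariant_counts_exclusive(self):
        rng = np.random.default_rng(17)
        tree = simulate_coalescent_tree(3, 1.0, rng)
        m = matrix_for(tree, ["A", "C", "G"])
        with pytest.raises(ValueError, match="mutually exclusive"):
            tree_log_likelihood(
                tree, ClockModel(), TN93Params(), m,
                ascertainment=True, invariant_counts={"A": 3},
            )


class TestCoalescentPrior:
    def test_two_leaf_closed_form(self):
        for t, N in [(0.7, 1.0), (2.0, 0.5), (0.1, 3.0)]:
            lp = coalescent_log_prior(two_leaf_tree(t), CoalescentParams(N))
            assert np.isclose(lp, -t / N - np.log(N), atol=1e-12)

    def test_three_leaf_interval_product(self):
        t1, t2, N = 0.3, 1.1, 1.7
        tree = three_leaf_tree(t1, t2)
        lp = coalescent_log_prior(tree, CoalescentParams(N))
        expect = -3 * t1 / N - (t2 - t1) / N - 2 * np.log(N)
        assert np.isclose(lp, expect, atol=1e-12)

    def test_pop_size_crossover(self):
        short, long_ = two_leaf_tree(0.01), two_leaf_tree(10.0)
        assert coalescent_log_prior(
            short, CoalescentParams(1.0)
        ) > coalescent_log_prior(short, CoalescentParams(2.0))
        assert coalescent_log_prior(
            long_, CoalescentParams(2.0)
        ) > coalescent_log_prior(long_, CoalescentParams(1.0))

    def test_nonpositive_pop_size_rejected(self):
        with pytest.raises(ValueError):
            CoalescentParams(0.0)


class TestBranchRates:
    def test_strict_clock_gives_ones(self):
        r = draw_branch_rates(ClockModel(), 7, 0)
        assert np.all(r == 1.0)

    def test_zero_sigma_relaxed_is_degenerate(self):
        clock = ClockModel(kind="lognormal_relaxed", sigma=0.0)
        assert np.all(draw_branch_rates(clock, 7, 0) == 1.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ClockModel(kind="lognormal_relaxed", sigma=-0.5)

    def test_mean_one_at_large_sample(self):
        clock = ClockModel(kind="lognormal_relaxed", sigma=0.5)
        r = draw_branch_rates(clock, 100_000, 42)
        sd = np.sqrt(np.exp(0.25) - 1.0)
        assert abs(r.mean() - 1.0) < 3 * sd / np.sqrt(len(r))
        assert np.all(r > 0)

    def test_reproducible_under_seed(self):
        clock = ClockModel(kind="lognormal_relaxed", sigma=0.8,
                           n_rate_categories=10)
        a = draw_branch_rates(clock, 50, 7)
        b = draw_branch_rates(clock, 50, 7)
        assert np.array_equal(a, b)
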