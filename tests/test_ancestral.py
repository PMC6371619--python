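"""Joint ancestral sampling, per-clade tallies, and the catalogue."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from conftest import matrix_for, three_leaf_tree
from phyloallele.ancestral import (
    AncestorCatalogue,
    NodeAlleleTally,
    PredictedAllele,
    assign_node_labels,
    best_ancestors,
    build_catalogue,
    sample_ancestral_alleles,
    second_best_gap,
    tally_node_alleles,
)
from phyloallele.mcmc import PosteriorSample, mcc_tree
from phyloallele.phylo_model import (
    ClockModel,
    CoalescentParams,
    TN93Params,
    effective_branch_lengths,
    encode_leaf_states,
    transition_matrices,
)
from phyloallele.simulate import simulate_coalescent_tree


def as_sample(tree, params=None, clock=None):
    return PosteriorSample(
        tree=tree, params=params or TN93Params(),
        clock=clock or ClockModel(), coal=CoalescentParams(1.0),
        log_posterior=0.0, log_likelihood=0.0, log_prior=0.0,
    )


class TestSampleAncestralAlleles:
    def test_only_internal_nodes_returned_leaves_clamped(self):
        tree = simulate_coalescent_tree(4, 1.0, 1)
        m = matrix_for(tree, ["AC", "AC", "AG", "AG"])
        drawn = sample_ancestral_alleles(as_sample(tree), m, rng_seed=0)
        assert set(drawn) == {4, 5, 6}
        assert all(len(s) == 2 for s in drawn.values())

    def test_near_zero_mutation_copies_shared_allele(self):
        tree = three_leaf_tree(1e-9, 2e-9)
        m = matrix_for(tree, ["ACG", "ACG", "ACG"])
        sample = as_sample(tree)
        hits = 0
        rng = np.random.default_rng(3)
        for _ in range(1000):
            drawn = sample_ancestral_alleles(sample, m, rng)
            hits += all(v == "ACG" for v in drawn.values())
        assert hits >= 990

    def test_root_marginal_matches_pruning_closed_form(self):
        """3 leaves, 1 site: empirical root-state frequencies over 10^4
        joint draws agree with the enumerated root posterior within 3 SE."""
        tree = three_leaf_tree(0.4, 1.2)
        params = TN93Params(pi=np.array([0.3, 0.2, 0.2, 0.3]), kappa1=3.0)
        clock = ClockModel(mean_rate=0.5)
        m = matrix_for(tree, ["A", "G", "C"])
        # closed-form root posterior by enumeration over the other internal
        ls = encode_leaf_states(m, tree.taxa)
        P = transition_matrices(
            params, effective_branch_lengths(tree, clock)
        )
        post = np.zeros(4)
        for root_state in range(4):
            tot = 0.0
            for mid in range(4):
                pr = P[3][root_state, mid]
                pr *= P[0][mid, ls[0, 0]] * P[1][mid, ls[1, 0]]
                pr *= P[2][root_state, ls[2, 0]]
                tot += pr
            post[root_state] = params.pi[root_state] * tot
        post /= post.sum()

        sample = as_sample(tree, params, clock)
        rng = np.random.default_rng(4)
        n = 10_000
        counts = Counter(
            sample_ancestral_alleles(sample, m, rng)[tree.root]
            for _ in range(n)
        )
        for i, nuc in enumerate("ACGT"):
            freq = counts.get(nuc, 0) / n
            se = np.sqrt(post[i] * (1 - post[i]) / n)
            assert abs(freq - post[i]) < 3 * se + 1e-4

    def test_taxa_mismatch_rejected(self):
        tree = simulate_coalescent_tree(3, 1.0, 2)
        m = matrix_for(["x", "y", "z"], ["A", "C", "G"])
        with pytest.raises(ValueError):
            sample_ancestral_alleles(as_sample(tree), m, 0)

    def test_sites_with_identical_patterns_drawn_independently(self):
        # two columns with the same leaf pattern must not be perfectly
        # correlated in the joint draw
        tree = three_leaf_tree(0.5, 1.5)
        clock = ClockModel(mean_rate=1.0)
        m = matrix_for(tree, ["AA", "GG", "CC"])
        sample = as_sample(tree, clock=clock)
        rng = np.random.default_rng(5)
        disagree = sum(
            (lambda d: d[tree.root][0] != d[tree.root][1])(
                sample_ancestral_alleles(sample, m, rng)
            )
            for _ in range(400)
        )
        assert disagree > 0


class TestTally:
    def test_single_sample_single_allele_posterior_one(self):
        tree = simulate_coalescent_tree(4, 1.0, 7)
        m = matrix_for(tree, ["AC", "AC", "AG", "AG"])
        samples = [as_sample(tree)]
        mcc = mcc_tree(samples)
        tallies = tally_node_alleles(samples, m, mcc, rng_seed=1)
        for t in tallies:
            assert t.n_clade_samples == 1
            assert list(t.counts.values()) == [1]
            assert sum(t.posteriors.values()) == 1.0

    def test_counts_are_conditional_on_clade_presence(self):
        from test_mcmc import four_taxon_tree

        t1, t2 = four_taxon_tree("ab|cd"), four_taxon_tree("ac|bd")
        m = matrix_for(["a", "b", "c", "d"], ["A", "A", "A", "A"])
        samples = [as_sample(t1), as_sample(t1), as_sample(t2)]
        tallies = tally_node_alleles(
            samples, m, {frozenset("ab"), frozenset("abcd")}, rng_seed=2
        )
        by_clade = {t.clade: t for t in tallies}
        assert by_clade[frozenset("ab")].n_clade_samples == 2
        assert by_clade[frozenset("abcd")].n_clade_samples == 3

    def test_posteriors_sum_to_one_exactly(self):
        tree = simulate_coalescent_tree(5, 1.0, 8)
        rngst = np.random.default_rng(9)
        m = matrix_for(
            tree, ["".join(rngst.choice(list("ACGT"), 4)) for _ in range(5)]
        )
        samples = [as_sample(tree) for _ in range(7)]
        tallies = tally_node_alleles(samples, m, mcc_tree(samples),
                                     rng_seed=3)
        for t in tallies:
            assert sum(t.counts.values()) == t.n_clade_samples

    def test_absent_clade_dropped_with_warning(self):
        tree = simulate_coalescent_tree(4, 1.0, 10)
        m = matrix_for(tree, ["A", "A", "C", "C"])
        ghost = frozenset({tree.taxa[0], "nobody"})
        with pytest.warns(UserWarning, match="no sample"):
            tallies = tally_node_alleles(
                [as_sample(tree)], m, {ghost}, rng_seed=0
            )
        assert tallies == []

    def test_deterministic_under_seed(self):
        tree = simulate_coalescent_tree(5, 1.0, 11)
        m = matrix_for(tree, ["AC", "AG", "CC", "CA", "AT"])
        samples = [as_sample(tree) for _ in range(5)]
        mcc = mcc_tree(samples)
        a = tally_node_alleles(samples, m, mcc, rng_seed=5)
        b = tally_node_alleles(samples, m, mcc, rng_seed=5)
        assert [(t.clade, t.counts) for t in a] == \
            [(t.clade, t.counts) for t in b]


class TestBestAncestors:
    def test_mode_with_lexicographic_tie_break(self):
        t = NodeAlleleTally(clade=frozenset("ab"),
                            counts={"GG": 2, "AA": 2}, n_clade_samples=4)
        states, post = t.mode()
        assert (states, post) == ("AA", 0.5)

    def test_status_reflects_observed_membership(self):
        tallies = [
            NodeAlleleTally(clade=frozenset("ab"), counts={"AC": 3},
                            n_clade_samples=3),
            NodeAlleleTally(clade=frozenset("cd"), counts={"GT": 2, "AC": 1},
                            n_clade_samples=3),
        ]
        best = best_ancestors(tallies, observed=["AC"])
        by_clade = {e.clade: e for e in best}
        assert by_clade[frozenset("ab")].status == "observed"
        assert by_clade[frozenset("cd")].status == "predicted"
        assert by_clade[frozenset("cd")].posterior == pytest.approx(2 / 3)

    def test_empty_tallies_rejected(self):
        with pytest.raises(ValueError):
            best_ancestors([], observed=[])


class TestCatalogue:
    def tallies(self):
        return [
            NodeAlleleTally(clade=frozenset("ab"),
                            counts={"AA": 6, "AC": 3, "GG": 1},
                            n_clade_samples=10),
            NodeAlleleTally(clade=frozenset("abc"),
                            counts={"AA": 2, "CC": 2},
                            n_clade_samples=4),
        ]

    def test_threshold_filters_and_sorts(self):
        cat = build_catalogue(self.tallies(), observed=["AC"], threshold=0.2)
        posts = [e.posterior for e in cat.entries]
        assert posts == sorted(posts, reverse=True)
        assert all(e.posterior >= 0.2 for e in cat.entries)
        assert {e.states for e in cat.entries} == {"AA", "AC", "CC"}

    def test_size_nonincreasing_in_threshold(self):
        sizes = [
            build_catalogue(self.tallies(), observed=[], threshold=th).n_entries
            for th in [0.0, 0.1, 0.3, 0.55, 0.9]
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_unique_by_states_keeps_max_posterior(self):
        cat = build_catalogue(self.tallies(), observed=[], threshold=0.0)
        uniq = {e.states: e.posterior for e in cat.unique_by_states()}
        assert uniq["AA"] == 0.6  # max over the two nodes (0.6 vs 0.5)
        assert cat.n_unique_states <= cat.n_entries
        per_node_unique = sum(len(t.counts) for t in self.tallies())
        assert cat.n_unique_states <= per_node_unique

    def test_status_assignment_and_weights(self):
        cat = build_catalogue(self.tallies(), observed=["AA"], threshold=0.0)
        assert cat.weight_of("AA") == 1.0
        assert cat.weight_of("AC") == 0.3
        with pytest.raises(KeyError):
            cat.weight_of("TT")

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_catalogue(self.tallies(), observed=[], threshold=1.0)

    def test_tsv_round_trip(self, tmp_path):
        cat = build_catalogue(self.tallies(), observed=["AA"], threshold=0.0)
        path = tmp_path / "cat.tsv"
        cat.to_tsv(path, reference="AA")
        back = AncestorCatalogue.from_tsv(path)
        assert [(e.states, e.posterior, e.status) for e in back.entries] == \
            [(e.states, round(e.posterior, 6), e.status)
             for e in cat.entries]


class TestSecondBestGap:
    def test_single_allele(self):
        t = NodeAlleleTally(clade=frozenset("a"), counts={"AA": 5},
                            n_clade_samples=5)
        assert second_best_gap(t) == (1.0, 0.0)

    def test_three_to_one(self):
        t = NodeAlleleTally(clade=frozenset("a"), counts={"AA": 3, "CC": 1},
                            n_clade_samples=4)
        assert second_best_gap(t) == (0.75, 0.25)


class TestNodeLabels:
    def test_preorder_letters_above_support_floor(self):
        tree = simulate_coalescent_tree(5, 1.0, 12)
        samples = [as_sample(tree) for _ in range(2)]
        summary = mcc_tree(samples)
        labels = assign_node_labels(summary, support_floor=0.5)
        assert len(labels) == 4  # all internal clades at support 1.0
        assert sorted(labels.values()) == ["A", "B", "C", "D"]
        # root clade labelled first in preorder
        assert labels[frozenset(tree.taxa)] == "A"


class TestRecoveryAtTrueTree:
    def test_modal_root_allele_recovers_truth_in_concentrated_regime(self):
        """With the true tree and parameters at study-like per-site
        diversity, the modal jointly-sampled root allele is the true
        ancestral allele."""
        from phyloallele.simulate import SimulationConfig, simulate_dataset

        model = TN93Params(pi=np.array([0.3, 0.2, 0.2, 0.3]), kappa1=4.0,
                           kappa2=2.0)
        hits = 0
        for seed in [11, 22, 33, 44]:
            truth = simulate_dataset(SimulationConfig(
                n_alleles=20, mutation_rate=0.01, seq_length=200,
                model=model, seed=seed, outgroup_divergence=0.5,
            ))
            m = truth.to_variant_matrix()
            sample = as_sample(truth.tree, model,
                               ClockModel(mean_rate=0.01))
            rng = np.random.default_rng(6)
            mrca = truth.ingroup_mrca
            counts = Counter(
                sample_ancestral_alleles(sample, m, rng)[mrca]
                for _ in range(200)
            )
            modal = counts.most_common(1)[0][0]
            hits += modal == truth.node_variant_states(mrca)
        assert hits >= 3
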