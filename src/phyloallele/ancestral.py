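"""Ancestral allele reconstruction and the predicted-allele catalogue.

For every posterior draw, ancestral states at each internal node are sampled
jointly by the standard stochastic backtrace: an upward pruning pass gives
conditional likelihoods, the root state is drawn from its posterior, and
states are then drawn conditionally down the tree, per site.  A node's
sampled ancestral *allele* is the concatenation of its per-site draws.

Node identity across sampled topologies is the clade (the set of ingroup
taxa below the node): for each internal clade of the summary (MCC) tree, the
sampled ancestral allele is tallied over exactly those posterior samples
whose tree contains that clade.  The tally's normalized counts are the
allele-level posterior probabilities; an allele is "observed" if it matches
a sampled taxon's allele and "predicted" otherwise.  Ranking all tallied
(allele, node) pairs by posterior yields the ancestor catalogue from which
unobserved alleles are proposed.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mcmc import MCCTree
from .phylo_model import (
    TN93Params,
    compute_partials,
    effective_branch_lengths,
    encode_leaf_states,
    transition_matrices,
)
from .trees import CladeKey
from .variant_matrix import AlleleString, encode_variant_string

__all__ = [
    "NodeAlleleTally",
    "PredictedAllele",
    "AncestorCatalogue",
    "sample_ancestral_alleles",
    "tally_node_alleles",
    "best_ancestors",
    "build_catalogue",
    "second_best_gap",
    "assign_node_labels",
]

_NUC = np.array(list("ACGT"))


@dataclass
class NodeAlleleTally:
    """Distribution of sampled ancestral alleles at one clade."""

    clade: CladeKey
    counts: dict  # states string -> number of samples
    n_clade_samples: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_clade_samples:
            raise ValueError("tally counts do not sum to n_clade_samples")

    @property
    def posteriors(self) -> dict:
        return {a: c / self.n_clade_samples for a, c in self.counts.items()}

    def mode(self) -> tuple[str, float]:
        """Most probable allele; ties broken by lexicographically smallest
        states string."""
        best = min(self.counts, key=lambda a: (-self.counts[a], a))
        return best, self.counts[best] / self.n_clade_samples


@dataclass
class PredictedAllele:
    """A candidate ancestral allele at a named clade."""

    states: str
    clade: CladeKey
    posterior: float
    status: str  # "observed" | "predicted"
    node_label: str = ""
    source_rank: int = 1

    def as_allele(self) -> AlleleString:
        return AlleleString(states=self.states, label=self.node_label or "anc",
                            status=self.status)


@dataclass
class AncestorCatalogue:
    """Ranked (allele, clade) candidates above a posterior floor.

    ``entries`` is sorted by posterior descending (ties by node label then
    states); :meth:`unique_by_states` deduplicates alleles appearing at
    several nodes, keeping each allele's maximum posterior.
    """

    entries: list  # list[PredictedAllele]
    threshold: float = 0.0
    observed_states: set = field(default_factory=set)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_unique_states(self) -> int:
        return len({e.states for e in self.entries})

    def unique_by_states(self) -> list:
        best: dict = {}
        for e in self.entries:
            cur = best.get(e.states)
            if cur is None or e.posterior > cur.posterior:
                best[e.states] = e
        return sorted(
            best.values(), key=lambda e: (-e.posterior, e.node_label, e.states)
        )

    def all_states(self) -> set:
        return {e.states for e in self.entries} | set(self.observed_states)

    def weight_of(self, states: str) -> float:
        """Phasing weight: 1 for experimentally observed alleles, the
        catalogue posterior (max across nodes) for predicted ones."""
        if states in self.observed_states:
            return 1.0
        w = [e.posterior for e in self.entries if e.states == states]
        if not w:
            raise KeyError(f"allele {states!r} not in catalogue")
        return max(w)

    def to_tsv(self, path, reference: str | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(
                "node_label\tclade\tvariant_string\tstates\tposterior"
                "\tstatus\tcross_reference\n"
            )
            for e in self.entries:
                dash = (
                    encode_variant_string(e.states, reference)
                    if reference
                    else ""
                )
                fh.write(
                    f"{e.node_label}\t{';'.join(sorted(e.clade))}\t{dash}\t"
                    f"{e.states}\t{e.posterior:.6g}\t{e.status}\t\n"
                )

    @classmethod
    def from_tsv(cls, path, observed=()) -> "AncestorCatalogue":
        obs = _observed_set(observed)
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            col = {c: i for i, c in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                clade = frozenset(
                    x for x in parts[col["clade"]].split(";") if x
                )
                entries.append(
                    PredictedAllele(
                        states=parts[col["states"]],
                        clade=clade,
                        posterior=float(parts[col["posterior"]]),
                        status=parts[col["status"]],
                        node_label=parts[col["node_label"]],
                    )
                )
        obs |= {e.states for e in entries if e.status == "observed"}
        return cls(entries=entries, observed_states=obs)


def sample_ancestral_alleles(sample, matrix, rng_seed) -> dict[int, str]:
    """Jointly sample ancestral states at every internal node of one
    posterior draw; returns node id -> states string.  Leaves are clamped to
    their observed alleles, so only internal nodes appear in the result."""
    tree = sample.tree
    if set(tree.taxa) != set(matrix.names):
        raise ValueError("sample tree taxa do not match matrix alleles")
    rng = np.random.default_rng(rng_seed)
    params: TN93Params = sample.params
    leaf_states = encode_leaf_states(matrix, tree.taxa)
    n_sites = leaf_states.shape[1]
    eff = effective_branch_lengths(tree, sample.clock)
    P = transition_matrices(params, eff)
    pats, inv, _ = np.unique(
        leaf_states, axis=1, return_inverse=True, return_counts=True
    )
    partials, _ = compute_partials(tree, P, pats)
    root = tree.root
    drawn = np.zeros((tree.n_nodes, n_sites), dtype=np.int8)
    drawn[: tree.n_leaves] = leaf_states

    def draw_rows(prob: np.ndarray) -> np.ndarray:
        c = prob.cumsum(axis=1)
        u = rng.random(prob.shape[0]) * c[:, -1]
        return (u[:, None] > c).sum(axis=1).astype(np.int8)

    root_post = partials[root] * params.pi  # (n_patterns, 4)
    drawn[root] = draw_rows(root_post[inv])
    for node in tree.preorder():
        if node == root or tree.children[node, 0] < 0:
            continue
        ps = drawn[tree.parent[node]]
        prob = P[node][ps] * partials[node][inv]
        drawn[node] = draw_rows(prob)
    return {
        int(v): "".join(_NUC[drawn[v]])
        for v in range(tree.n_nodes)
        if tree.children[v, 0] >= 0
    }


def tally_node_alleles(
    samples,
    matrix,
    clades,
    rng_seed,
    n_draws: int = 1,
) -> list[NodeAlleleTally]:
    """Tally jointly sampled ancestral alleles per clade of the summary tree.

    ``clades`` is an :class:`~phyloallele.mcmc.MCCTree` or an iterable of
    CladeKeys.  Each clade is tallied over exactly the samples whose tree
    contains it (the conditional-on-clade denominator); a clade present in
    no sample is dropped with a warning.  ``n_draws`` joint draws are taken
    per posterior sample (more draws reduce tally Monte Carlo noise without
    changing the estimated posterior).
    """
    if isinstance(clades, MCCTree):
        targets = set(clades.tree.clades().values())
    else:
        targets = set(clades)
    if not samples:
        raise ValueError("need at least one posterior sample")
    rng = np.random.default_rng(rng_seed)
    counts: dict = {key: {} for key in targets}
    totals: dict = {key: 0 for key in targets}
    for s in samples:
        sample_clades = s.tree.clades()
        for _ in range(n_draws):
            drawn = sample_ancestral_alleles(s, matrix, rng)
            for node, key in sample_clades.items():
                if key in targets:
                    allele = drawn[node]
                    counts[key][allele] = counts[key].get(allele, 0) + 1
                    totals[key] += 1
    out = []
    for key in targets:
        if totals[key] == 0:
            warnings.warn(f"clade {sorted(key)} present in no sample; dropped")
            continue
        out.append(
            NodeAlleleTally(
                clade=key, counts=counts[key], n_clade_samples=totals[key]
            )
        )
    out.sort(key=lambda t: (-len(t.clade), sorted(t.clade)))
    return out


def _status(states: str, observed: set) -> str:
    return "observed" if states in observed else "predicted"


def _observed_set(observed) -> set:
    out = set()
    for a in observed:
        out.add(a.states if isinstance(a, AlleleString) else str(a))
    return out


def best_ancestors(
    tallies, observed, labels: dict | None = None
) -> list[PredictedAllele]:
    """The modal ancestral allele of each node with its posterior.

    The same allele may be best at several nodes with different posteriors
    (clades are tallied independently).  Status is "observed" when the modal
    allele coincides with a sampled taxon's allele.
    """
    if not tallies:
        raise ValueError("no tallies given")
    obs = _observed_set(observed)
    labels = labels or {}
    out = []
    for t in tallies:
        states, post = t.mode()
        out.append(
            PredictedAllele(
                states=states,
                clade=t.clade,
                posterior=post,
                status=_status(states, obs),
                node_label=labels.get(t.clade, ""),
                source_rank=1,
            )
        )
    return out


def build_catalogue(
    tallies,
    observed,
    threshold: float = 0.0,
    labels: dict | None = None,
) -> AncestorCatalogue:
    """Collect every tallied (allele, node) pair with posterior >= threshold
    into a ranked catalogue."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    obs = _observed_set(observed)
    labels = labels or {}
    entries = []
    for t in tallies:
        ranked = sorted(t.posteriors.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (states, post) in enumerate(ranked, start=1):
            if post >= threshold:
                entries.append(
                    PredictedAllele(
                        states=states,
                        clade=t.clade,
                        posterior=post,
                        status=_status(states, obs),
                        node_label=labels.get(t.clade, ""),
                        source_rank=rank,
                    )
                )
    entries.sort(key=lambda e: (-e.posterior, e.node_label, e.states))
    return AncestorCatalogue(
        entries=entries, threshold=threshold, observed_states=obs
    )


def second_best_gap(tally: NodeAlleleTally) -> tuple[float, float]:
    """The two largest allele posteriors at a node (second is 0 when only
    one allele was ever sampled)."""
    if not tally.counts:
        raise ValueError("empty tally")
    post = sorted(tally.posteriors.values(), reverse=True)
    return post[0], post[1] if len(post) > 1 else 0.0


def assign_node_labels(mcc: MCCTree, support_floor: float = 0.5) -> dict:
    """Cosmetic letter labels (A, B, C, ...) for the summary tree's internal
    clades with support above ``support_floor``, in preorder."""
    labels: dict = {}
    letters = list(string.ascii_uppercase)
    clades = mcc.tree.clades()
    i = 0
    for node in mcc.tree.preorder():
        key = clades.get(node)
        if key is None:
            continue
        if mcc.supports.get(key, 0.0) >= support_floor:
            if i < len(letters):
                labels[key] = letters[i]
            else:
                labels[key] = f"N{i + 1}"
            i += 1
    return labels
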