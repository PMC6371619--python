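"""Metropolis–Hastings sampler over coalescent time-trees.

State: rooted time-tree (topology + node heights), TN93 kappas, coalescent
population size; base frequencies are empirical and the clock's mean rate is
the unit of time (rate and population size are confounded without
calibration, so the tree is measured in expected substitutions per site).

Proposal kit: narrow and wide subtree exchanges, uniform node-height moves,
root-gap and whole-tree scalers, and log-uniform multiplier scalers on the
scalar parameters.  All scalers use a log-uniform multiplier f =
exp(lambda*(u-1/2)), whose Hastings term for scaling d coordinates at once
is d*log(f).

If an outgroup taxon is declared it is constrained to attach at the root
(its parent is always the root node), which roots the ingroup subtree, and
proposals that would move it are rejected outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.spatial.distance import squareform

from .phylo_model import (
    ClockModel,
    CoalescentParams,
    TN93Params,
    coalescent_log_prior,
    draw_branch_rates,
    tree_log_likelihood,
)
from .simulate import attach_outgroup
from .trees import CladeKey, TimeTree, from_linkage
from .variant_matrix import hamming

__all__ = [
    "MCMCConfig",
    "Priors",
    "PosteriorSample",
    "MCMCResult",
    "run_mcmc",
    "effective_sample_size",
    "clade_supports",
    "mcc_tree",
    "MCCTree",
    "upgma_start_tree",
]


@dataclass
class MCMCConfig:
    chain_length: int = 200_000
    sample_every: int = 200
    burn_in_fraction: float = 0.10
    seed: int = 1
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not (self.chain_length >= self.sample_every >= 1):
            raise ValueError("need chain_length >= sample_every >= 1")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_samples(self) -> int:
        """Samples per chain: one at generation 0, then every
        ``sample_every`` generations."""
        return self.chain_length // self.sample_every + 1


@dataclass
class Priors:
    """Priors on the sampled scalars (the reference analysis reported only
    'default parameters', so these are this package's own weakly informative
    choices, exposed as configuration)."""

    kappa: object = field(
        default_factory=lambda: stats.lognorm(s=1.25, scale=np.exp(1.0))
    )
    # population size in tree time units spans orders of magnitude depending
    # on how the data scale time (substitutions/site here), so its prior is
    # close to scale-free: lognormal with median 1 and log-sd 4
    pop_size: object = field(
        default_factory=lambda: stats.lognorm(s=4.0, scale=1.0)
    )

    def log_kappa(self, x: float) -> float:
        return float(self.kappa.logpdf(x))

    def log_pop_size(self, x: float) -> float:
        return float(self.pop_size.logpdf(x))


@dataclass
class PosteriorSample:
    """One MCMC draw."""

    tree: TimeTree
    params: TN93Params
    clock: ClockModel
    coal: CoalescentParams
    log_posterior: float
    log_likelihood: float
    log_prior: float
    generation: int = 0
    chain: int = 0


@dataclass
class MCCTree:
    """Maximum clade credibility tree with per-clade annotations."""

    tree: TimeTree
    supports: dict
    mean_heights: dict

    def clade_nodes(self) -> dict[int, CladeKey]:
        return self.tree.clades()

    def newick(self) -> str:
        ann = {}
        for node, key in self.tree.clades().items():
            s = self.supports.get(key, 0.0)
            h = self.mean_heights.get(key, float(self.tree.heights[node]))
            ann[node] = f"[&support={s:.4g},height={h:.6g}]"
        return self.tree.newick(annotations=ann)


@dataclass
class MCMCResult:
    chains: list  # list of list[PosteriorSample]
    trace: pd.DataFrame
    config: MCMCConfig

    def samples(self, burn_in_fraction: float | None = None) -> list:
        """Post-burn-in samples pooled across chains (burn-in per chain)."""
        frac = (
            self.config.burn_in_fraction
            if burn_in_fraction is None
            else burn_in_fraction
        )
        out = []
        for chain in self.chains:
            out.extend(chain[int(np.ceil(len(chain) * frac)):])
        return out


def upgma_start_tree(matrix) -> TimeTree:
    """UPGMA tree on variant-site p-distances — a reasonable ultrametric
    starting state.  The outgroup, if present, is grafted onto the ingroup
    root afterwards so the root constraint holds from generation 0."""
    names = matrix.ingroup_names
    k = max(matrix.n_sites, 1)
    if matrix.invariant_base_counts:
        k += sum(matrix.invariant_base_counts.values())
    d = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            d[i, j] = d[j, i] = hamming(
                matrix.states_of(a), matrix.states_of(names[j])
            ) / k
    jitter = 1e-4 * (1 + np.arange(len(names)))[:, None]
    d = d + jitter + jitter.T  # break exact ties deterministically
    np.fill_diagonal(d, 0.0)
    Z = upgma_linkage(squareform(d, checks=False))
    tree = from_linkage(Z, names)
    if matrix.outgroup_name is not None:
        og = matrix.states_of(matrix.outgroup_name)
        mean_d = float(
            np.mean([hamming(og, matrix.states_of(nm)) for nm in names])
        ) / k
        root_h = tree.heights[tree.root]
        gap = max(mean_d / 2.0 - root_h, 0.1 * (root_h + 1e-3))
        tree = attach_outgroup(tree, gap, name=matrix.outgroup_name)
        tree.outgroup = matrix.outgroup_name
    tree.validate()
    return tree


class _State:
    __slots__ = ("tree", "kappa1", "kappa2", "pop_size",
                 "log_likelihood", "log_coal", "log_param_prior")

    def __init__(self, tree, kappa1, kappa2, pop_size):
        self.tree = tree
        self.kappa1 = kappa1
        self.kappa2 = kappa2
        self.pop_size = pop_size


def _scaler(rng, lam: float = 0.7) -> float:
    return float(np.exp(lam * (rng.random() - 0.5)))


def run_mcmc(
    matrix,
    config: MCMCConfig,
    *,
    clock: ClockModel | None = None,
    params: TN93Params | None = None,
    coal: CoalescentParams | None = None,
    priors: Priors | None = None,
    ascertainment: bool = False,
    invariant_counts: dict | None = None,
    sample_kappas: bool = True,
    sample_pop_size: bool = True,
    start_tree: TimeTree | None = None,
) -> MCMCResult:
    """Sample (tree, kappa1, kappa2, pop_size) from the posterior.

    Deterministic for a given (config.seed, config); chain i uses seed
    config.seed + i.  Samples are emitted at generation 0 and then every
    ``config.sample_every`` generations.
    """
    if len(matrix.ingroup_names) < 3:
        raise ValueError("need at least 3 ingroup taxa")
    clock = clock or ClockModel()
    priors = priors or Priors()
    params0 = params or TN93Params.from_empirical(matrix)
    coal0 = coal  # None -> initialized per chain from the start tree scale
    chains, traces = [], []
    for c in range(config.n_chains):
        samples, tr = _run_chain(
            matrix, config, chain_id=c, seed=config.seed + c, clock=clock,
            params0=params0, coal0=coal0, priors=priors,
            ascertainment=ascertainment, invariant_counts=invariant_counts,
            sample_kappas=sample_kappas,
            sample_pop_size=sample_pop_size, start_tree=start_tree,
        )
        chains.append(samples)
        traces.append(tr)
    trace = pd.concat(traces, ignore_index=True)
    return MCMCResult(chains=chains, trace=trace, config=config)


def _run_chain(matrix, config, *, chain_id, seed, clock, params0, coal0,
               priors, ascertainment, invariant_counts, sample_kappas,
               sample_pop_size, start_tree):
    rng = np.random.default_rng(seed)
    tree = (start_tree or upgma_start_tree(matrix)).copy()
    if clock.kind == "lognormal_relaxed" and clock.sigma > 0:
        rates = draw_branch_rates(clock, tree.n_nodes, rng)
        rates[tree.root] = 1.0
        tree.rates = rates
    likelihood_clock = ClockModel(
        kind="strict", mean_rate=clock.mean_rate
    )  # multipliers live on tree.rates

    if coal0 is None:
        # E[TMRCA] = 2N, so half the start tree's height is a sane scale
        pop0 = max(float(tree.heights[tree.root]) / 2.0, 1e-9)
    else:
        pop0 = coal0.pop_size
    state = _State(tree, params0.kappa1, params0.kappa2, pop0)
    pi = params0.pi

    def ll_of(st) -> float:
        p = TN93Params(pi=pi, kappa1=st.kappa1, kappa2=st.kappa2)
        return tree_log_likelihood(
            st.tree, likelihood_clock, p, matrix,
            ascertainment=ascertainment, invariant_counts=invariant_counts,
        )

    def coal_of(st) -> float:
        return coalescent_log_prior(st.tree, CoalescentParams(st.pop_size))

    def param_prior_of(st) -> float:
        lp = priors.log_pop_size(st.pop_size)
        if sample_kappas:
            lp += priors.log_kappa(st.kappa1) + priors.log_kappa(st.kappa2)
        return lp

    state.log_likelihood = ll_of(state)
    state.log_coal = coal_of(state)
    state.log_param_prior = param_prior_of(state)

    n = tree.n_leaves
    og_leaf = tree.taxa.index(tree.outgroup) if tree.outgroup else -1
    internal = np.flatnonzero(tree.children[:, 0] >= 0)
    n_internal = len(internal)

    moves: list[tuple[str, float]] = [
        ("node_height", float(n)),
        ("root_height", 2.0),
        ("tree_scale", 2.0),
        ("narrow", float(n)),
        ("wide", max(1.0, n / 3.0)),
    ]
    if sample_kappas:
        moves += [("kappa1", max(2.0, n / 4)), ("kappa2", max(2.0, n / 4))]
    if sample_pop_size:
        moves += [("pop_size", max(2.0, n / 4))]
    if clock.kind == "lognormal_relaxed" and clock.sigma > 0:
        moves += [("rate_swap", n / 2.0)]
    names = [m for m, _ in moves]
    w = np.array([x for _, x in moves])
    w /= w.sum()

    samples: list[PosteriorSample] = []
    records = []

    def record(gen):
        lp = state.log_likelihood + state.log_coal + state.log_param_prior
        samples.append(
            PosteriorSample(
                tree=state.tree.copy(),
                params=TN93Params(pi=pi, kappa1=state.kappa1, kappa2=state.kappa2),
                clock=clock,
                coal=CoalescentParams(state.pop_size),
                log_posterior=lp,
                log_likelihood=state.log_likelihood,
                log_prior=state.log_coal + state.log_param_prior,
                generation=gen,
                chain=chain_id,
            )
        )
        records.append(
            dict(
                chain=chain_id,
                generation=gen,
                log_posterior=lp,
                log_likelihood=state.log_likelihood,
                log_prior=state.log_coal + state.log_param_prior,
                kappa1=state.kappa1,
                kappa2=state.kappa2,
                pop_size=state.pop_size,
                root_height=float(state.tree.heights[state.tree.root]),
                tree_length=state.tree.total_length(),
            )
        )

    record(0)
    n_accept = 0
    for gen in range(1, config.chain_length + 1):
        move = names[rng.choice(len(names), p=w)]
        accepted = _propose_and_decide(
            move, state, rng, og_leaf, internal, n_internal,
            ll_of, coal_of, param_prior_of, sample_kappas,
        )
        n_accept += accepted
        if gen % config.sample_every == 0:
            record(gen)

    trace = pd.DataFrame.from_records(records)
    trace["acceptance_rate"] = n_accept / max(config.chain_length, 1)
    return samples, trace


def _propose_and_decide(move, state, rng, og_leaf, internal, n_internal,
                        ll_of, coal_of, param_prior_of, sample_kappas) -> int:
    tree = state.tree
    new = _State(tree, state.kappa1, state.kappa2, state.pop_size)
    log_h = 0.0
    tree_changed = False
    kappa_changed = False
    pop_changed = False

    if move in ("kappa1", "kappa2"):
        f = _scaler(rng)
        log_h = np.log(f)
        setattr(new, move, getattr(state, move) * f)
        kappa_changed = True
    elif move == "pop_size":
        f = _scaler(rng)
        log_h = np.log(f)
        new.pop_size = state.pop_size * f
        pop_changed = True
    else:
        t2 = tree.copy()
        ok, log_h = _tree_move(move, t2, rng, og_leaf, internal, n_internal)
        if not ok:
            return 0
        new.tree = t2
        tree_changed = True

    new.log_likelihood = (
        ll_of(new) if (tree_changed or kappa_changed) else state.log_likelihood
    )
    new.log_coal = coal_of(new) if (tree_changed or pop_changed) else state.log_coal
    new.log_param_prior = (
        param_prior_of(new) if (kappa_changed or pop_changed)
        else state.log_param_prior
    )
    delta = (
        new.log_likelihood + new.log_coal + new.log_param_prior
        - state.log_likelihood - state.log_coal - state.log_param_prior
    )
    if np.log(rng.random()) < delta + log_h:
        state.tree = new.tree
        state.kappa1, state.kappa2 = new.kappa1, new.kappa2
        state.pop_size = new.pop_size
        state.log_likelihood = new.log_likelihood
        state.log_coal = new.log_coal
        state.log_param_prior = new.log_param_prior
        return 1
    return 0


def _tree_move(move, tree, rng, og_leaf, internal, n_internal):
    """Apply a topology/height move in place; returns (valid, log_hastings)."""
    h = tree.heights
    root = tree.root
    if move == "node_height":
        cand = internal[internal != root]
        if len(cand) == 0:
            return False, 0.0
        v = int(rng.choice(cand))
        lo = float(h[tree.children[v]].max())
        hi = float(h[tree.parent[v]])
        h[v] = lo + rng.random() * (hi - lo)
        return True, 0.0
    if move == "root_height":
        lo = float(h[tree.children[root]].max())
        gap = float(h[root]) - lo
        if gap <= 0:
            return False, 0.0
        f = _scaler(rng)
        h[root] = lo + gap * f
        return True, float(np.log(f))
    if move == "tree_scale":
        f = _scaler(rng, lam=0.3)
        h[internal] *= f
        # scaling can only break parent>child if leaves are not at height 0
        leaf_h = np.delete(h, internal)
        if leaf_h.size and leaf_h.max() > 0:
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p >= 0 and h[p] <= h[v]:
                    return False, 0.0
        return True, float(n_internal * np.log(f))
    if move == "narrow":
        cand = internal[internal != root]
        if len(cand) == 0:
            return False, 0.0
        p = int(rng.choice(cand))
        g = int(tree.parent[p])
        sibs = tree.children[g]
        u = int(sibs[1] if sibs[0] == p else sibs[0])
        c = int(tree.children[p][int(rng.random() < 0.5)])
        if u == og_leaf or c == og_leaf:
            return False, 0.0
        if not (h[g] > h[c] and h[p] > h[u]):
            return False, 0.0
        _swap_subtrees(tree, c, u)
        return True, 0.0
    if move == "wide":
        nn = tree.n_nodes
        i = int(rng.integers(nn))
        j = int(rng.integers(nn))
        if i == j or i == root or j == root or og_leaf in (i, j):
            return False, 0.0
        pi_, pj = int(tree.parent[i]), int(tree.parent[j])
        if pi_ == pj:
            return False, 0.0
        if _is_ancestor(tree, i, j) or _is_ancestor(tree, j, i):
            return False, 0.0
        if not (h[pi_] > h[j] and h[pj] > h[i]):
            return False, 0.0
        _swap_subtrees(tree, i, j)
        return True, 0.0
    if move == "rate_swap":
        nn = tree.n_nodes
        i = int(rng.integers(nn))
        j = int(rng.integers(nn))
        if i == j or i == root or j == root:
            return False, 0.0
        tree.rates[i], tree.rates[j] = tree.rates[j], tree.rates[i]
        return True, 0.0
    raise ValueError(f"unknown move {move!r}")


def _swap_subtrees(tree, a: int, b: int) -> None:
    pa, pb = int(tree.parent[a]), int(tree.parent[b])
    ca, cb = tree.children[pa], tree.children[pb]
    ca[int(ca[1] == a)] = b
    cb[int(cb[1] == b)] = a
    tree.parent[a], tree.parent[b] = pb, pa


def _is_ancestor(tree, a: int, b: int) -> bool:
    v = b
    while v >= 0:
        if v == a:
            return True
        v = int(tree.parent[v])
    return False


# -- diagnostics ------------------------------------------------------------------


def effective_sample_size(trace) -> float:
    """Autocorrelation-time ESS using Geyer's initial positive sequence.

    A perfectly constant trace is degenerate (no information about mixing);
    it is reported as ESS = n with a warning.
    """
    x = np.asarray(trace, dtype=np.float64)
    n = x.size
    if n < 10:
        raise ValueError("trace too short for ESS (need >= 10)")
    v = x.var()
    if v == 0:
        warnings.warn("degenerate (constant) trace; reporting ESS = n")
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = -1.0
    for k in range(0, n // 2):
        gamma = rho[2 * k] + (rho[2 * k + 1] if 2 * k + 1 < n else 0.0)
        if gamma <= 0:
            break
        tau += 2.0 * gamma
    tau = max(tau, 1e-6)
    return float(n / tau)


# -- tree summaries ---------------------------------------------------------------


def _post_burn_in(samples, burn_in_fraction: float):
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    kept = samples[int(np.ceil(len(samples) * burn_in_fraction)):]
    if not kept:
        raise ValueError("no samples remain after burn-in")
    return kept


def clade_supports(samples, burn_in_fraction: float = 0.0) -> dict:
    """CladeKey -> fraction of post-burn-in samples whose tree contains it."""
    kept = _post_burn_in(samples, burn_in_fraction)
    counts: dict = {}
    for s in kept:
        for key in set(s.tree.clades().values()):
            counts[key] = counts.get(key, 0) + 1
    return {k: c / len(kept) for k, c in counts.items()}


def mcc_tree(samples, burn_in_fraction: float = 0.0) -> MCCTree:
    """Maximum clade credibility tree.

    Among the sampled trees, returns the one maximizing the sum of log clade
    supports; ties go to the earliest-sampled tree.  Node heights are
    annotated with the mean height of each clade across the samples that
    contain it.
    """
    kept = _post_burn_in(samples, burn_in_fraction)
    supports = clade_supports(kept, 0.0)
    h_sums: dict = {}
    h_counts: dict = {}
    for s in kept:
        for node, key in s.tree.clades().items():
            h_sums[key] = h_sums.get(key, 0.0) + float(s.tree.heights[node])
            h_counts[key] = h_counts.get(key, 0) + 1
    mean_heights = {k: h_sums[k] / h_counts[k] for k in h_sums}
    best, best_score = None, -np.inf
    for s in kept:
        score = sum(np.log(supports[k]) for k in s.tree.clades().values())
        if score > best_score + 1e-12:
            best, best_score = s, score
    return MCCTree(tree=best.tree.copy(), supports=supports,
                   mean_heights=mean_heights)
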