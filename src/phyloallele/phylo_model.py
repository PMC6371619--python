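"""Substitution model, molecular clocks, likelihood, and the coalescent prior.

The substitution process is TN93 (Tamura–Nei): a reversible nucleotide model
with arbitrary stationary base frequencies and separate purine (A<->G) and
pyrimidine (C<->T) transition rate multipliers ``kappa1`` and ``kappa2``
relative to transversions.  The generator is normalized so branch lengths are
expected substitutions per site.

Transition probabilities are computed by symmetric eigendecomposition of the
normalized generator — exact for any reversible model and vectorizable over
many branch lengths at once, which is what the MCMC needs.

The tree prior is the constant-size coalescent: with ``k`` extant lineages,
the waiting time to the next coalescence is Exponential(k(k-1)/(2N)), and
each coalescence contributes a factor 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trees import TimeTree

__all__ = [
    "NUC_ORDER",
    "TN93Params",
    "ClockModel",
    "CoalescentParams",
    "tn93_rate_matrix",
    "tn93_transition_probs",
    "transition_matrices",
    "encode_leaf_states",
    "compute_partials",
    "tree_log_likelihood",
    "coalescent_log_prior",
    "draw_branch_rates",
]

NUC_ORDER = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUC_ORDER)}
_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T


@dataclass
class TN93Params:
    """TN93 parameters: base frequencies and the two transition/transversion
    rate ratios (kappa1 for purines, kappa2 for pyrimidines).

    kappa1 == kappa2 reduces to HKY; kappa1 == kappa2 == 1 with uniform
    frequencies reduces to JC69.
    """

    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa1: float = 2.0
    kappa2: float = 2.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if self.pi.shape != (4,) or not np.all(self.pi > 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must sum to 1 (got {self.pi.sum()})")
        if not (self.kappa1 > 0 and self.kappa2 > 0):
            raise ValueError("kappa1 and kappa2 must be positive")

    @classmethod
    def from_empirical(cls, matrix, kappa1: float = 2.0, kappa2: float = 2.0,
                       pseudocount: float = 0.5) -> "TN93Params":
        """Base frequencies counted from the ingroup variant-site states."""
        counts = np.full(4, pseudocount)
        for name in matrix.ingroup_names:
            for c in matrix.states_of(name):
                counts[_NUC_INDEX[c]] += 1
        return cls(pi=counts / counts.sum(), kappa1=kappa1, kappa2=kappa2)

    def _eigensystem(self):
        Q = tn93_rate_matrix(self)
        d = np.sqrt(self.pi)
        S = (Q * d[:, None]) / d[None, :]  # symmetric for reversible Q
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        A = V / d[:, None]  # D^-1 V
        B = V.T * d[None, :]  # V^T D
        return w, A, B


def tn93_rate_matrix(params: TN93Params) -> np.ndarray:
    """Normalized TN93 generator (expected 1 substitution/site/unit time)."""
    pi, k1, k2 = params.pi, params.kappa1, params.kappa2
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if i in _PURINES and j in _PURINES:
                rate *= k1
            elif i in _PYRIMIDINES and j in _PYRIMIDINES:
                rate *= k2
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def tn93_transition_probs(params: TN93Params, t) -> np.ndarray:
    """P(t) for one branch length or an array of them.

    Rows sum to 1; P(0) = I; P(s)P(t) = P(s+t); rows tend to pi as t grows.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("branch length must be nonnegative")
    w, A, B = params._eigensystem()
    E = np.exp(np.multiply.outer(t, w))  # (..., 4)
    P = np.einsum("ij,...j,jk->...ik", A, E, B)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=-1, keepdims=True)
    return P


@dataclass
class ClockModel:
    """Molecular clock: strict, or discretized uncorrelated-lognormal relaxed.

    ``mean_rate`` converts tree time into expected substitutions/site;
    ``sigma`` is the stdev (in log space) of the mean-1 lognormal from which
    per-branch rate multipliers are drawn; the relaxed clock is discretized
    into ``n_rate_categories`` equal-probability quantile midpoints
    (default: one category per branch).
    """

    kind: str = "strict"  # "strict" | "lognormal_relaxed"
    mean_rate: float = 1.0
    sigma: float = 0.0
    n_rate_categories: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "lognormal_relaxed"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if not self.mean_rate > 0:
            raise ValueError("mean_rate must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def rate_category_multipliers(sigma: float, n_categories: int) -> np.ndarray:
    """Quantile midpoints of the mean-1 lognormal, one per category."""
    if sigma == 0:
        return np.ones(n_categories)
    dist = stats.lognorm(s=sigma, scale=np.exp(-(sigma**2) / 2.0))
    q = (np.arange(n_categories) + 0.5) / n_categories
    return dist.ppf(q)


def draw_branch_rates(clock: ClockModel, n_branches: int, rng) -> np.ndarray:
    """Per-branch rate multipliers; strict clock (or sigma=0) gives all ones.

    For the relaxed clock each branch is assigned one of the discretized
    lognormal category multipliers; when the number of categories equals the
    number of branches each category is used exactly once (a random
    permutation), otherwise categories are drawn uniformly.
    """
    if n_branches < 1:
        raise ValueError("need at least one branch")
    rng = np.random.default_rng(rng)
    if clock.kind == "strict" or clock.sigma == 0:
        return np.ones(n_branches)
    K = clock.n_rate_categories or n_branches
    mult = rate_category_multipliers(clock.sigma, K)
    if K == n_branches:
        return mult[rng.permutation(K)]
    return mult[rng.integers(0, K, size=n_branches)]


# -- pruning likelihood -----------------------------------------------------------


def encode_leaf_states(matrix, taxa: list[str]) -> np.ndarray:
    """(n_leaves, n_sites) int8 array of 0..3 states in NUC_ORDER, rows
    aligned with ``taxa``."""
    lut = np.full(128, -1, dtype=np.int8)
    for c, i in _NUC_INDEX.items():
        lut[ord(c)] = i
    rows = []
    for name in taxa:
        s = np.frombuffer(matrix.states_of(name).encode(), dtype=np.uint8)
        rows.append(lut[s])
    out = np.array(rows, dtype=np.int8)
    if (out < 0).any():
        raise ValueError("leaf states outside A/C/G/T")
    return out


def effective_branch_lengths(tree: TimeTree, clock: ClockModel) -> np.ndarray:
    """Expected substitutions/site on the branch above each node."""
    return tree.branch_lengths() * clock.mean_rate * tree.rates


def transition_matrices(params: TN93Params, eff_lengths: np.ndarray) -> np.ndarray:
    return tn93_transition_probs(params, eff_lengths)


def compute_partials(
    tree: TimeTree,
    P: np.ndarray,
    leaf_states: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Felsenstein pruning pass.

    Returns ``(partials, log_scale)``: ``partials[v, s, x]`` is the scaled
    conditional likelihood of the data below node ``v`` at site ``s`` given
    state ``x``; ``log_scale[s]`` accumulates the per-site log of the
    rescaling factors applied to avoid underflow.
    """
    n_nodes = tree.n_nodes
    n_leaves = tree.n_leaves
    n_sites = leaf_states.shape[1]
    partials = np.zeros((n_nodes, n_sites, 4))
    idx = np.arange(n_sites)
    for leaf in range(n_leaves):
        wild = leaf_states[leaf] < 0  # -1 marginalizes the leaf
        partials[leaf, idx, np.where(wild, 0, leaf_states[leaf])] = 1.0
        if wild.any():
            partials[leaf, wild, :] = 1.0
    log_scale = np.zeros(n_sites)
    for node in tree.postorder():
        l, r = tree.children[node]
        if l < 0:
            continue
        down_l = partials[l] @ P[l].T  # (sites, 4): sum_j P[x, j] L_l[j]
        down_r = partials[r] @ P[r].T
        p = down_l * down_r
        mx = p.max(axis=1)
        small = mx < 1e-140
        if small.any():
            safe = np.where(mx > 0, mx, 1.0)
            p[small] /= safe[small, None]
            log_scale[small] += np.log(safe[small])
        partials[node] = p
    return partials, log_scale


def _pattern_compress(leaf_states: np.ndarray):
    pats, inverse, weights = np.unique(
        leaf_states, axis=1, return_inverse=True, return_counts=True
    )
    return pats, inverse, weights


def tree_log_likelihood(
    tree: TimeTree,
    clock: ClockModel,
    params: TN93Params,
    matrix,
    ascertainment: bool = False,
    invariant_counts: dict | None = None,
) -> float:
    """Log-likelihood of the variant matrix on the tree (sites independent).

    Three treatments of the fact that the matrix holds only the variable
    columns of a longer alignment:

    * plain (default): the variant columns are the whole dataset;
    * ``ascertainment=True``: condition on each site being variable among
      the ingroup, dividing each site's likelihood by 1 - P(constant);
    * ``invariant_counts={'A': nA, ...}``: the full-alignment likelihood —
      each ingroup-invariant column of shared base x contributes
      log P(all ingroup leaves = x), the outgroup marginalized there
      (its states at invariant columns are not retained).

    The last is the most informative (invariant columns calibrate branch
    lengths) and excludes ``ascertainment``.
    """
    if ascertainment and invariant_counts:
        raise ValueError(
            "ascertainment and invariant_counts are mutually exclusive"
        )
    taxa_in_matrix = set(matrix.names)
    if set(tree.taxa) != taxa_in_matrix:
        raise ValueError("tree taxa do not match matrix alleles")
    leaf_states = encode_leaf_states(matrix, tree.taxa)
    eff = effective_branch_lengths(tree, clock)
    P = transition_matrices(params, eff)
    pats, _, weights = _pattern_compress(leaf_states)
    partials, log_scale = compute_partials(tree, P, pats)
    root = tree.root
    site_lik = partials[root] @ params.pi
    ll = float(np.dot(weights, np.log(site_lik) + log_scale))
    if ascertainment or invariant_counts:
        # per-base probability of an ingroup-constant column (outgroup
        # marginalized: it never makes a column variable by itself)
        const = np.tile(np.arange(4, dtype=np.int8), (tree.n_leaves, 1))
        og = getattr(matrix, "outgroup_name", None)
        if og is not None and og in tree.taxa:
            const[tree.taxa.index(og), :] = -1
        cp, cs = compute_partials(tree, P, const)
        p_const_x = (cp[root] @ params.pi) * np.exp(cs)
        if ascertainment:
            p_const = min(float(p_const_x.sum()), 1.0 - 1e-12)
            ll -= float(weights.sum()) * np.log1p(-p_const)
        else:
            counts = np.array(
                [invariant_counts.get(c, 0) for c in NUC_ORDER], dtype=float
            )
            ll += float(np.dot(counts, np.log(np.maximum(p_const_x, 1e-300))))
    return ll


# -- coalescent prior -------------------------------------------------------------


@dataclass
class CoalescentParams:
    """Constant effective population size, in the tree's time units."""

    pop_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.pop_size > 0:
            raise ValueError("pop_size must be positive")


def coalescent_log_prior(tree: TimeTree, coal: CoalescentParams) -> float:
    """Log-density of the tree under the constant-size coalescent.

    Working backward in time, each inter-event interval with k lineages and
    duration tau contributes -k(k-1)/2 * tau/N, and each coalescence a
    further -log N.
    """
    N = coal.pop_size
    n = tree.n_leaves
    is_leaf = tree.children[:, 0] < 0
    events = sorted(
        range(tree.n_nodes),
        key=lambda v: (tree.heights[v], 0 if is_leaf[v] else 1),
    )
    log_p = 0.0
    k = 0
    t_prev = tree.heights[events[0]]
    for v in events:
        t = tree.heights[v]
        if k >= 2:
            log_p -= k * (k - 1) / 2.0 * (t - t_prev) / N
        t_prev = t
        if is_leaf[v]:
            k += 1
        else:
            k -= 1
            log_p -= np.log(N)
    return float(log_p)
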