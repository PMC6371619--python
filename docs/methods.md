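# Methods

`phyloallele` turns a panel of experimentally verified alleles of one long
gene into (i) a Bayesian coalescent phylogeny, (ii) a catalogue of
*predicted* ancestral alleles with posterior probabilities, and (iii) a
phasing engine that explains unphased diploid genotypes as pairs of
observed or predicted alleles with quantified confidence. This note
documents the models, the defaults and why, the numerical choices, what the
synthetic data emulate, and the limitations.

## Data model

An *allele* is one haplotype of the locus, represented by its states at the
variable alignment columns (the variant sites). Input is a pre-aligned
multi-FASTA; columns with ≥ 2 distinct states among the ingroup rows are
extracted (`extract_variant_sites`). The outgroup never creates variant
sites by itself (flag `include_outgroup_in_variability` to change this);
its states at the selected columns are carried along for rooting. Site
positions are reported as 1-based alignment columns; alleles interconvert
between full states and the dash notation, where `-` means "identical to
the reference allele at this site". Gap columns shared by all rows are
dropped; partial gaps are an input error — indels and IUPAC ambiguity codes
are not modelled.

## Phylogenetic model

**Substitution.** TN93: reversible, arbitrary stationary frequencies `pi`,
separate purine (`kappa1`) and pyrimidine (`kappa2`)
transition/transversion rate ratios. The generator is normalized so branch
lengths are expected substitutions per site. Transition probabilities come
from the symmetric eigendecomposition of the normalized generator (exact
for any reversible model, vectorized over all branches at once). `pi`
defaults to empirical counts over the ingroup variant sites with a 0.5
pseudocount per base.

**Clock.** Strict by default (`mean_rate` = 1, so tree time is measured in
substitutions per site). The relaxed clock is the discretized
uncorrelated-lognormal variant: per-branch multipliers are quantile
midpoints of a mean-1 lognormal with log-sd `sigma`, one category per
branch by default. The relaxed clock mainly affects branch lengths, not the
allele-enumeration logic, which is why the strict clock is the testing
default.

**Tree prior.** Constant-size coalescent: with `k` lineages an interval of
duration `tau` contributes `-k(k-1)/2 * tau/N`, each coalescence `-log N`.

**Likelihood.** Felsenstein pruning over the variant sites (sites
independent, patterns compressed, per-node rescaling below 1e-140 guards
underflow). Because the matrix holds only the variable columns of a longer
alignment, three treatments are offered: plain (the variant columns are
the dataset — the default, mirroring common practice for extracted variant
sites); an ascertainment correction that conditions each site on being
variable among the ingroup (divides by `1 - P(constant)`, outgroup
marginalized); and the full-alignment likelihood via the recorded per-base
counts of invariant columns, where each ingroup-invariant column of shared
base `x` contributes `log P(all ingroup = x)` (outgroup marginalized
there, as its states at invariant columns are not retained). The last is
exact — it equals pruning on the reconstructed full alignment, which a
test asserts — and is what the package's own simulation-recovery studies
use: invariant columns carry most of the branch-length information, and
discarding them measurably degrades both parameter calibration and
ancestral-state accuracy.

## MCMC

Metropolis–Hastings over (topology, node heights, `kappa1`, `kappa2`,
`N`). Proposals: uniform node-height moves, root-gap and whole-tree
scalers, narrow and wide subtree exchanges, and log-uniform multiplier
scalers on the scalars (a scaler touching `d` coordinates has Hastings term
`d*log f`). One generation = one proposal; samples are recorded at
generation 0 and every `sample_every` generations, so a chain of length `L`
thinned by `s` yields `L/s + 1` samples. Chains are deterministic given
(seed, config); chain `i` of a multi-chain run uses `seed + i`, and burn-in
(default 10%) applies per chain.

The start tree is UPGMA on variant-site p-distances (deterministic
tie-nudging), with the outgroup grafted onto the ingroup root. If an
outgroup is declared it is constrained to attach at the root throughout —
proposals that would move it are rejected — which roots the ingroup.

Priors are configuration, defaulting to weakly informative choices:
lognormal(meanlog 1, sdlog 1.25) on each kappa, and a near-scale-free
lognormal(median 1, log-sd 4) on `N`, because the time scale of the tree
(substitutions/site here) varies by orders of magnitude across datasets.
`N` is initialized at half the start tree's root height (E[TMRCA] = 2N)
so the chain starts at the data's scale.

Sampler correctness is tested two ways: with the likelihood forced flat
the chain reproduces closed-form coalescent moments (TMRCA, total length),
and on a 4-taxon dataset its topology posterior matches
likelihood-weighted draws from the coalescent prior (importance sampling)
within Monte Carlo error.

Convergence diagnostics: autocorrelation ESS with Geyer's initial positive
sequence; a constant trace is reported as ESS = n with a warning.

**MCC tree.** The maximum clade credibility tree is the *sampled* tree
maximizing the sum of log clade supports (support = fraction of
post-burn-in samples containing the clade, clades keyed by their ingroup
taxon set); ties go to the earliest sample. Per-clade mean heights are
reported as annotations rather than overwriting the sampled tree's heights,
since per-clade means need not be jointly monotone.

## Ancestral alleles and the catalogue

For each posterior sample, ancestral states are drawn *jointly* by the
standard stochastic backtrace (root from its posterior, then conditionally
down the tree, per site); a node's sampled allele is the concatenation of
its per-site draws. Sites sharing a leaf pattern share pruning work but are
drawn independently.

Node identity across topologies is the clade (ingroup taxon set). For each
internal clade of the MCC tree, sampled alleles are tallied over exactly
the samples whose tree contains that clade (conditional-on-clade
denominator), one joint draw per posterior sample. This is why the same
allele can be the best ancestor at two nodes with different posteriors.
Ties anywhere break to the lexicographically smallest states string, for
determinism.

The catalogue collects every tallied (allele, node) pair with posterior ≥
threshold (default export threshold 0.10), sorted by posterior descending;
a deduplicated-by-states view keeps each allele's maximum posterior. An
entry is *observed* if its states match a sampled taxon's allele,
*predicted* otherwise. Both the pair count and the unique-states count are
reported. Letter labels (A, B, ...) are cosmetic, assigned in preorder to
MCC clades with support above 0.5.

## Phasing and the update loop

A genotype is an unordered state pair per variant site (`None` = no-call,
constraining nothing — an extension beyond the verified-allele workflow).
The locus is treated as one fully linked haplotype block (no
recombination). `compatible_pairs` enumerates exhaustively the template
pairs whose site-wise union equals the genotype; a pair scores
`w(a) * w(b)` with `w = 1` for observed alleles and `w = posterior` for
predicted ones; confidence is the top score over the sum. When nothing
phases, `flag_novel` proposes the site-wise complement of each viable
single template (complements closest to the catalogue first); if every
template mismatches more than half the heterozygous sites it warns and
returns nothing. `update_catalogue` inserts a confirmed allele as observed
(idempotent; a matching predicted entry is promoted), closing the loop:
confirm, re-catalogue, phase again.

Two predicted alleles in a pair multiply their posteriors; there is no
minimum reportable confidence (both are configuration).

## Synthetic data

`simulate_coalescent_tree` delegates to msprime (haploid samples, constant
population size); sequence evolution runs in-package so every internal
node's sequence is recorded. A `single_hit` mode restricts each site to at
most one mutation tree-wide for clean oracle tests; the default is exact
TN93 (multiple hits possible), matching the inference model.

The study preset (`make_study_fixture`) emulates the motivating data's
shape: 48 ingroup alleles over 21,406 sites, mutation rate 3.8e-4 per site
per coalescent time unit (chosen from Watterson's formula to yield ~72
segregating sites), outgroup joining 4N above the ingroup root (~0.005
substitutions/site of separation). Because the segregating-site count has
sd ≈ 22 at these dimensions, the preset deterministically iterates over
sub-seeds derived from the given seed until the count lands in 60–90,
keeping the closest draw if the bounded attempt budget runs out.

The recovery studies (`phyloallele.evaluation`) use a reduced 20-taxon /
200-site preset with per-site diversity 2Nmu = 0.02 and an outgroup 0.5N
above the root. These values were chosen to reproduce the *posterior
concentration regime* of real long-gene allele panels — most variable
sites with a near-certain ancestral state, joint node-allele posteriors
roughly 0.2–0.95 — which is the regime in which enumerating ancestral
alleles is meaningful. Replicates are analyzed with the full-alignment
likelihood (variant columns plus invariant-base counts). Chains are 12,000
generations thinned by 30 (these sizes keep a 20-replicate study to a few
minutes; they are the package's own desk-scale choice, not a fidelity
claim). What passing recovery tests
show: at this scaled-down, correctly specified regime the pipeline is
calibrated (the 95% interval covers the true kappa1), recovers the true
root allele as the modal tallied ancestor, and surfaces it near the top of
the predicted catalogue. What they do not show: robustness to model
misspecification (recombination, rate heterogeneity, alignment error,
population structure), none of which the generator emulates.

"Posterior median within the central 95% interval" is operationalized here
as the standard calibration check: the *true* parameter value lies within
the central 95% posterior credible interval.

## Numerical choices

- Transition probabilities are clipped at 0 and row-renormalized after the
  eigendecomposition (guards 1e-16-scale negatives).
- Pruning rescales per site when the maximum partial drops below 1e-140.
- UPGMA distances get a deterministic 1e-4-scale asymmetric-pair nudge so
  linkage ties cannot depend on row order.
- The ascertainment probability of a constant site is capped at 1 - 1e-12.
- Catalogue ordering: posterior desc, then node label, then states; tally
  modes break ties lexicographically.
- All randomness flows from user-supplied integer seeds through
  numpy Generators; msprime sub-seeds are drawn below 2^31.

## Limitations

- No recombination (detection or simulation); recombinant alleles enter
  the catalogue as plain entries if present in the data.
- No rate heterogeneity across sites, codon/partition models, or
  tip dating; IUPAC ambiguity codes and indels are rejected at input.
- The clade-keyed tally conditions on clade presence; clades rare in the
  posterior get noisy allele posteriors (their sample counts are reported).
- The relaxed clock's category assignments are sampled by swap moves with
  fixed `sigma`; `sigma` itself is not sampled.
- The CLI writes strict-clock NEXUS tree samples (no per-branch rate
  annotations); relaxed-clock analyses are for the library API.
- Phasing enumerates template pairs exhaustively: fine for catalogues of
  thousands, quadratic beyond that.

## Pipeline configuration (CLI `all`)

```toml
seed = 7
[simulate]          # optional: replace with [input] fasta/reference/outgroup
preset = "small"
[mcmc]
chain_length = 50000
sample_every = 100
chains = 4
site_likelihood = "plain"   # or "ascertainment" / "full"
burn_in = 0.1
[ancestors]
threshold = 0.10
[phase]             # optional
genotypes = "genotypes.tsv"
```
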