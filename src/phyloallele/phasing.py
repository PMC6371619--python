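"""Phasing diploid genotypes against a catalogue of alleles.

A genotype over the variant sites is an unordered pair of states per site.
Because the locus is treated as one fully linked haplotype block (no
recombination), phasing reduces to finding ordered-free pairs of template
alleles whose site-wise union reproduces the genotype.  Templates come from
the combined catalogue of experimentally confirmed (observed) alleles and
phylogenetically predicted ancestors; a pair's score is the product of its
member weights — 1 for observed alleles, the catalogue posterior for
predicted ones — and the reported confidence is the top score normalized
over all compatible pairs.

When no template pair explains a genotype, the complement of each viable
single template is proposed as a candidate novel allele; once such an
allele is experimentally confirmed it is inserted into the catalogue as
observed, closing the loop: the previously unphaseable genotype then
phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .ancestral import AncestorCatalogue, PredictedAllele
from .variant_matrix import AlleleString, hamming

__all__ = [
    "Genotype",
    "PhasingResult",
    "compatible_pairs",
    "score_pairs",
    "phase",
    "flag_novel",
    "update_catalogue",
    "read_genotypes_tsv",
    "read_genotypes_vcf",
]

_NUCS = frozenset("ACGT")


@dataclass(frozen=True)
class Genotype:
    """Unphased diploid genotype: one unordered state pair per variant site.

    A site may be ``None`` (no-call), which constrains nothing.
    """

    pairs: tuple  # tuple of (x, y) sorted tuples or None
    sample_id: str = ""

    def __post_init__(self) -> None:
        norm = []
        for p in self.pairs:
            if p is None:
                norm.append(None)
                continue
            x, y = p
            if x not in _NUCS or y not in _NUCS:
                raise ValueError(f"genotype states outside A/C/G/T: {p}")
            norm.append((x, y) if x <= y else (y, x))
        object.__setattr__(self, "pairs", tuple(norm))

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_alleles(cls, a, b, sample_id: str = "") -> "Genotype":
        """The genotype produced by merging two haplotypes."""
        sa = a.states if isinstance(a, AlleleString) else str(a)
        sb = b.states if isinstance(b, AlleleString) else str(b)
        if len(sa) != len(sb):
            raise ValueError("haplotype length mismatch")
        return cls(pairs=tuple(zip(sa, sb)), sample_id=sample_id)

    @property
    def het_sites(self) -> list[int]:
        return [
            i for i, p in enumerate(self.pairs) if p is not None and p[0] != p[1]
        ]

    def is_compatible_haplotype(self, states: str) -> bool:
        return all(
            p is None or states[i] in p for i, p in enumerate(self.pairs)
        )


@dataclass
class PhasingResult:
    """Ranked allele-pair explanations of one genotype."""

    sample_id: str
    ranked: list  # list of (states_a, states_b, score, status_a, status_b)
    confidence: float
    novel_candidates: list = field(default_factory=list)

    @property
    def best_pair(self):
        return (self.ranked[0][0], self.ranked[0][1]) if self.ranked else None


def _template_states(catalogue: AncestorCatalogue) -> list[str]:
    return sorted(catalogue.all_states())


def compatible_pairs(g: Genotype, catalogue: AncestorCatalogue) -> list:
    """All template pairs (a, b), a <= b lexicographically, whose site-wise
    union equals the genotype (no-call sites constrain nothing)."""
    templates = _template_states(catalogue)
    if templates and len(templates[0]) != len(g):
        raise ValueError("genotype length does not match catalogue alleles")
    singles = [t for t in templates if g.is_compatible_haplotype(t)]
    out = []
    for a, b in combinations_with_replacement(singles, 2):
        ok = True
        for i, p in enumerate(g.pairs):
            if p is None:
                continue
            x, y = a[i], b[i]
            if ((x, y) if x <= y else (y, x)) != p:
                ok = False
                break
        if ok:
            out.append((a, b))
    return out


def score_pairs(pairs, catalogue: AncestorCatalogue,
                sample_id: str = "") -> PhasingResult:
    """Score and rank compatible pairs; confidence = top score / sum."""
    def status(s):
        return "observed" if s in catalogue.observed_states else "predicted"

    scored = []
    for a, b in pairs:
        try:
            w = catalogue.weight_of(a) * catalogue.weight_of(b)
        except KeyError as exc:
            raise ValueError(f"pair member missing from catalogue: {exc}")
        scored.append((a, b, w, status(a), status(b)))
    scored.sort(key=lambda r: (-r[2], r[0], r[1]))
    total = sum(r[2] for r in scored)
    confidence = scored[0][2] / total if total > 0 else 0.0
    return PhasingResult(sample_id=sample_id, ranked=scored, confidence=confidence)


def phase(g: Genotype, catalogue: AncestorCatalogue) -> PhasingResult:
    """Convenience: enumerate and score compatible pairs; if none exist,
    attach novel-allele candidates."""
    result = score_pairs(compatible_pairs(g, catalogue), catalogue,
                         sample_id=g.sample_id)
    if not result.ranked:
        result.novel_candidates = flag_novel(g, catalogue)
    return result


def flag_novel(g: Genotype, catalogue: AncestorCatalogue,
               max_results: int = 5) -> list[PredictedAllele]:
    """Candidate novel alleles implied by the best partial explanations.

    For each catalogue allele compatible as one haplotype, the complement
    forced site-wise by the genotype is computed; complements absent from
    the catalogue are returned (closest-to-catalogue first, by hamming
    distance to their nearest entry).  If every catalogue allele mismatches
    the genotype at more than half of its heterozygous sites, no complement
    is trustworthy: an empty list is returned with a warning.
    """
    templates = _template_states(catalogue)
    het = g.het_sites
    viable = []  # (het_mismatch_fraction, template)
    for t in templates:
        hom_ok = all(
            p is None or p[0] != p[1] or t[i] == p[0]
            for i, p in enumerate(g.pairs)
        )
        if not hom_ok:
            continue
        mism = sum(1 for i in het if t[i] not in g.pairs[i])
        frac = mism / len(het) if het else 0.0
        viable.append((frac, t))
    if not viable or min(f for f, _ in viable) > 0.5:
        warnings.warn(
            f"genotype {g.sample_id or '?'} matches no catalogue allele at "
            ">=50% of heterozygous sites; no novel candidate proposed"
        )
        return []
    best_frac = min(f for f, _ in viable)
    cands: dict = {}
    for frac, t in viable:
        if frac > max(best_frac, 0.0):
            continue
        comp = []
        for i, p in enumerate(g.pairs):
            if p is None:
                comp.append(t[i])
            elif p[0] == p[1]:
                comp.append(p[0])
            elif t[i] in p:
                comp.append(p[1] if t[i] == p[0] else p[0])
            else:
                comp.append(p[0])  # unexplained site: deterministic choice
        c = "".join(comp)
        if c in catalogue.all_states():
            continue
        dist = min(hamming(c, s) for s in templates)
        if c not in cands or dist < cands[c][0]:
            cands[c] = (dist, t)
    ranked = sorted(cands.items(), key=lambda kv: (kv[1][0], kv[0]))
    return [
        PredictedAllele(
            states=c, clade=frozenset(), posterior=0.0, status="predicted",
            node_label="novel",
        )
        for c, _ in ranked[:max_results]
    ]


def update_catalogue(catalogue: AncestorCatalogue,
                     confirmed) -> AncestorCatalogue:
    """Insert an experimentally confirmed allele as observed (weight 1).

    A predicted entry with the same states is promoted to observed.
    Idempotent: inserting twice changes nothing further.
    """
    states = confirmed.states if isinstance(confirmed, AlleleString) else str(confirmed)
    if catalogue.entries and len(states) != len(catalogue.entries[0].states):
        raise ValueError("confirmed allele length does not match catalogue")
    entries = [
        PredictedAllele(
            states=e.states, clade=e.clade, posterior=e.posterior,
            status="observed" if e.states == states else e.status,
            node_label=e.node_label, source_rank=e.source_rank,
        )
        for e in catalogue.entries
    ]
    return AncestorCatalogue(
        entries=entries,
        threshold=catalogue.threshold,
        observed_states=set(catalogue.observed_states) | {states},
    )


# -- genotype I/O -----------------------------------------------------------------


def read_genotypes_tsv(path, site_positions: list[int]) -> list[Genotype]:
    """Read genotypes from a TSV with columns
    ``sample_id  site_position  state1  state2`` (missing sites -> no-call)."""
    pos_index = {p: i for i, p in enumerate(site_positions)}
    per_sample: dict = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["sample_id", "site_position", "state1", "state2"]:
            raise ValueError("unexpected genotype TSV header")
        for line in fh:
            sid, pos, s1, s2 = line.rstrip("\n").split("\t")[:4]
            if sid not in per_sample:
                per_sample[sid] = [None] * len(site_positions)
                order.append(sid)
            j = pos_index.get(int(pos))
            if j is None:
                raise ValueError(f"unknown site position {pos}")
            per_sample[sid][j] = (s1, s2)
    return [Genotype(pairs=tuple(per_sample[s]), sample_id=s) for s in order]


def read_genotypes_vcf(path, site_positions: list[int]) -> list[Genotype]:
    """Read diploid genotypes from a minimal VCF over the variant positions
    (one record per site, GT fields per sample)."""
    from cyvcf2 import VCF

    pos_index = {p: i for i, p in enumerate(site_positions)}
    vcf = VCF(str(path))
    names = list(vcf.samples)
    pairs: dict = {s: [None] * len(site_positions) for s in names}
    for v in vcf:
        j = pos_index.get(v.POS)
        if j is None:
            continue
        for s, gt in zip(names, v.gt_bases):
            sep = "|" if "|" in gt else "/"
            parts = gt.split(sep)
            if len(parts) == 2 and all(p in _NUCS for p in parts):
                pairs[s][j] = (parts[0], parts[1])
    return [Genotype(pairs=tuple(pairs[s]), sample_id=s) for s in names]
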