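"""Alignment ingest and variant-site bookkeeping.

A study locus here is a long (>20 kb) gene whose alleles differ at a handful
of variable positions.  This module reads a pre-aligned multi-FASTA of allele
sequences, finds the variable columns, and converts between three views of an
allele: the full sequence, its states at the variant sites only, and the
compact dash notation in which "-" means "identical to the reference allele
at this site".

Coordinates: ``site_positions`` are 1-based columns of the source alignment
(matching how variant tables in this literature list positions); all internal
indexing is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignedAlleleSet",
    "VariantMatrix",
    "AlleleString",
    "AlignmentError",
    "load_alignment",
    "extract_variant_sites",
    "encode_variant_string",
    "decode_variant_string",
    "hamming",
]

_NUCS = frozenset("ACGT")
_GAP = "-"


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, duplicates, bad characters)."""


@dataclass
class AlignedAlleleSet:
    """A set of same-length, same-locus allele sequences.

    ``outgroup_name`` flags one record (e.g. a chimpanzee orthologue) used
    for rooting; ``population_labels`` optionally tags each allele with the
    population it was sampled from.
    """

    names: list[str]
    sequences: list[str]
    outgroup_name: str | None = None
    population_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate allele names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.outgroup_name is not None and self.outgroup_name not in self.names:
            raise AlignmentError(f"outgroup {self.outgroup_name!r} not in alignment")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def ingroup_names(self) -> list[str]:
        return [n for n in self.names if n != self.outgroup_name]

    def sequence_of(self, name: str) -> str:
        return self.sequences[self.names.index(name)]


@dataclass
class VariantMatrix:
    """Taxa x variant-site matrix distilled from a full alignment."""

    names: list[str]
    states: list[str]  # per-allele string over the variant sites, same order
    site_positions: list[int]  # 1-based columns into the source alignment
    reference_name: str
    outgroup_name: str | None = None
    alignment_length: int | None = None
    #: counts of ingroup-invariant columns by their shared base (A,C,G,T);
    #: lets the likelihood use the full alignment, not just variant columns
    invariant_base_counts: dict | None = None

    def __post_init__(self) -> None:
        if self.reference_name not in self.names:
            raise ValueError(f"reference {self.reference_name!r} not in matrix")
        k = len(self.site_positions)
        if any(len(s) != k for s in self.states):
            raise ValueError("state strings do not match number of sites")
        if list(self.site_positions) != sorted(set(self.site_positions)):
            raise ValueError("site_positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def ingroup_names(self) -> list[str]:
        return [n for n in self.names if n != self.outgroup_name]

    @property
    def reference_states(self) -> str:
        return self.states[self.names.index(self.reference_name)]

    def states_of(self, name: str) -> str:
        return self.states[self.names.index(name)]

    def alleles(self, include_outgroup: bool = False) -> list["AlleleString"]:
        return [
            AlleleString(states=s, label=n, status="observed")
            for n, s in zip(self.names, self.states)
            if include_outgroup or n != self.outgroup_name
        ]

    @property
    def invariant_fraction(self) -> float:
        """Fraction of alignment columns that are invariant, in [0, 1]."""
        if self.alignment_length is None:
            raise ValueError("matrix does not record the source alignment length")
        return (self.alignment_length - self.n_sites) / self.alignment_length

    # -- tabular export ----------------------------------------------------------

    def to_tsv(self, path) -> None:
        ref = self.reference_states
        with open(path, "w") as fh:
            cols = "\t".join(f"site_{p}" for p in self.site_positions)
            fh.write(f"allele\t{cols}\tvariant_string\n")
            for name, s in zip(self.names, self.states):
                fh.write(
                    f"{name}\t" + "\t".join(s) + "\t"
                    + encode_variant_string(s, ref) + "\n"
                )

    def to_vcf_table(self, path, locus_name: str = "locus") -> None:
        """Minimal VCF-like site table with haploid per-allele calls."""
        ref = self.reference_states
        with open(path, "w") as fh:
            fh.write("CHROM\tPOS\tREF\tALT\t" + "\t".join(self.names) + "\n")
            for j, pos in enumerate(self.site_positions):
                col = [s[j] for s in self.states]
                alts = sorted(set(col) - {ref[j]})
                code = {ref[j]: "0"}
                code.update({a: str(i + 1) for i, a in enumerate(alts)})
                fh.write(
                    f"{locus_name}\t{pos}\t{ref[j]}\t{','.join(alts) or '.'}\t"
                    + "\t".join(code[c] for c in col) + "\n"
                )

    @classmethod
    def from_tsv(cls, path, reference_name: str, outgroup_name: str | None = None,
                 alignment_length: int | None = None) -> "VariantMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            site_cols = [c for c in header if c.startswith("site_")]
            positions = [int(c[5:]) for c in site_cols]
            names, states = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                names.append(parts[0])
                states.append("".join(parts[1 : 1 + len(site_cols)]))
        return cls(
            names=names,
            states=states,
            site_positions=positions,
            reference_name=reference_name,
            outgroup_name=outgroup_name,
            alignment_length=alignment_length,
        )


@dataclass(frozen=True)
class AlleleString:
    """One allele's states across the variant sites."""

    states: str
    label: str = ""
    status: str = "observed"  # "observed" | "predicted"

    def __post_init__(self) -> None:
        if not set(self.states) <= _NUCS:
            bad = sorted(set(self.states) - _NUCS)
            raise ValueError(f"allele states outside A/C/G/T: {bad}")
        if self.status not in ("observed", "predicted"):
            raise ValueError(f"bad status {self.status!r}")

    def __len__(self) -> int:
        return len(self.states)


def _states(x) -> str:
    return x.states if isinstance(x, AlleleString) else str(x)


def load_alignment(path, outgroup_name: str | None = None) -> AlignedAlleleSet:
    """Read a pre-aligned multi-FASTA of allele sequences.

    Sequences are upper-cased.  IUPAC ambiguity codes are rejected: the
    downstream model is defined over unambiguous A/C/G/T states (gaps are
    tolerated here only if later shared by every row, see
    :func:`extract_variant_sites`).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"need at least 2 records, got {len(records)}")
    names = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    allowed = _NUCS | {_GAP}
    for name, seq in zip(names, seqs):
        bad = set(seq) - allowed
        if bad:
            raise AlignmentError(
                f"record {name!r} contains unsupported characters {sorted(bad)} "
                "(IUPAC ambiguity codes are not modelled)"
            )
    return AlignedAlleleSet(names=names, sequences=seqs, outgroup_name=outgroup_name)


def extract_variant_sites(
    aln: AlignedAlleleSet,
    reference_name: str,
    include_outgroup_in_variability: bool = False,
) -> VariantMatrix:
    """Find the variable alignment columns and build the variant matrix.

    A column is variable when >= 2 distinct states occur among the counted
    rows; by default only ingroup rows are counted, so a divergent outgroup
    does not create variant sites by itself (its states at the selected
    columns are still carried along for rooting).  Columns gapped in every
    row are dropped; a gap in only some rows is an input error.
    """
    if reference_name not in aln.names:
        raise ValueError(f"reference {reference_name!r} not in alignment")
    arr = np.frombuffer(
        "".join(aln.sequences).encode(), dtype="S1"
    ).reshape(len(aln), aln.alignment_length)
    gap = arr == _GAP.encode()
    partial = gap.any(axis=0) & ~gap.all(axis=0)
    if partial.any():
        raise AlignmentError(
            f"column(s) {np.flatnonzero(partial)[:5] + 1} gapped in only part "
            "of the rows; indels are not modelled"
        )
    keep = ~gap.all(axis=0)
    counted = np.ones(len(aln), dtype=bool)
    if not include_outgroup_in_variability and aln.outgroup_name is not None:
        counted[aln.names.index(aln.outgroup_name)] = False
    sub = arr[counted][:, keep]
    variable = (sub != sub[0]).any(axis=0)
    cols = np.flatnonzero(keep)[variable]  # original 0-based columns
    if cols.size == 0:
        warnings.warn("alignment has no variable sites; empty matrix returned")
    states = ["".join(row) for row in arr[:, cols].astype("U1")]
    inv_bases = sub[0][~variable].astype("U1")
    invariant_counts = {
        c: int((inv_bases == c).sum()) for c in "ACGT"
    }
    return VariantMatrix(
        names=list(aln.names),
        states=states,
        site_positions=[int(c) + 1 for c in cols],
        reference_name=reference_name,
        outgroup_name=aln.outgroup_name,
        alignment_length=aln.alignment_length,
        invariant_base_counts=invariant_counts,
    )


def encode_variant_string(allele, reference) -> str:
    """Compact dash notation: "-" where the allele matches the reference."""
    a, r = _states(allele), _states(reference)
    if len(a) != len(r):
        raise ValueError(f"length mismatch: {len(a)} vs {len(r)}")
    return "".join("-" if x == y else x for x, y in zip(a, r))


def decode_variant_string(encoded: str, reference) -> str:
    """Inverse of :func:`encode_variant_string`."""
    r = _states(reference)
    if len(encoded) != len(r):
        raise ValueError(f"length mismatch: {len(encoded)} vs {len(r)}")
    bad = set(encoded) - (_NUCS | {_GAP})
    if bad:
        raise ValueError(f"illegal characters in variant string: {sorted(bad)}")
    return "".join(y if x == _GAP else x for x, y in zip(encoded, r))


def hamming(a, b) -> int:
    """Number of mismatching positions between two equal-length strings."""
    sa, sb = _states(a), _states(b)
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))
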