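"""Bundled reference data.

``ermap_node_ancestors.tsv`` holds the published per-node ancestral alleles
of the human ERMAP (Scianna blood group) phylogeny: the reference allele
(Allele1, GenBank KX265235) written out at the 72 variant positions, and the
13 labelled internal-node ancestors in dash notation with their posterior
probabilities, observed/predicted status and GenBank accessions where
applicable.
"""

from importlib import resources

import pandas as pd

from ..variant_matrix import AlleleString, decode_variant_string

__all__ = ["load_node_ancestors", "reference_allele"]


def _table_path():
    return resources.files(__package__) / "ermap_node_ancestors.tsv"


def load_node_ancestors() -> pd.DataFrame:
    """The published node-ancestor table with an extra ``states`` column
    (dash notation decoded against the reference allele)."""
    df = pd.read_csv(_table_path(), sep="\t", dtype={"posterior": float})
    ref = df.loc[df["node"] == "Reference", "variant_string"].iloc[0]
    df["states"] = [
        s if set(s) <= set("ACGT") else decode_variant_string(s, ref)
        for s in df["variant_string"]
    ]
    return df


def reference_allele() -> AlleleString:
    df = load_node_ancestors()
    row = df[df["node"] == "Reference"].iloc[0]
    return AlleleString(states=row["states"], label=row["allele"],
                        status="observed")
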