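"""The bundled published node-ancestor table of the human ERMAP phylogeny.

Thirteen labelled internal nodes with their best ancestral alleles in dash
notation against the reference allele (Allele1): four are observed alleles
that double as clade ancestors, the rest are predictions.
"""

from phyloallele.data import load_node_ancestors, reference_allele
from phyloallele.variant_matrix import hamming

table = load_node_ancestors()
ref = reference_allele()
print(f"reference: {ref.label} ({len(ref)} variant sites)\n")

nodes = table[table["node"] != "Reference"]
for _, row in nodes.iterrows():
    d = hamming(row["states"], ref.states)
    print(f"node {row['node']:>2}  {row['allele']:<9} "
          f"posterior {row['posterior']:.3f}  {row['status']:<9} "
          f"{d} diffs vs reference")

a = nodes[nodes["node"] == "A"].iloc[0]["states"]
b = nodes[nodes["node"] == "B"].iloc[0]["states"]
print(f"\nwhole-tree ancestor (node A) to node B ancestor: "
      f"{hamming(a, b)} substitution — single evolutionary steps "
      "separate adjacent node ancestors.")
print("Observed rows carry GenBank accessions; 'na' rows are predicted "
      "alleles awaiting experimental confirmation.")
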