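import numpy as np
import pytest

from phyloallele.trees import TimeTree
from phyloallele.variant_matrix import VariantMatrix


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_name, seq in records:
                fh.write(f">{rec_name}\n{seq}\n")
        return path

    return _write


def two_leaf_tree(height: float, taxa=("x", "y")) -> TimeTree:
    return TimeTree(
        taxa=list(taxa),
        parent=np.array([2, 2, -1]),
        children=np.array([[-1, -1], [-1, -1], [0, 1]]),
        heights=np.array([0.0, 0.0, height]),
    )


def three_leaf_tree(h1: float, h2: float, taxa=("a", "b", "c")) -> TimeTree:
    """((a,b):h1,c):h2 — cherry (a,b) at height h1, root at h2."""
    assert h2 > h1 > 0
    return TimeTree(
        taxa=list(taxa),
        parent=np.array([3, 3, 4, 4, -1]),
        children=np.array([[-1, -1], [-1, -1], [-1, -1], [0, 1], [3, 2]]),
        heights=np.array([0.0, 0.0, 0.0, h1, h2]),
    )


def matrix_for(tree_or_taxa, states, reference=None) -> VariantMatrix:
    taxa = getattr(tree_or_taxa, "taxa", tree_or_taxa)
    return VariantMatrix(
        names=list(taxa),
        states=list(states),
        site_positions=list(range(1, len(states[0]) + 1)),
        reference_name=reference or taxa[0],
    )
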