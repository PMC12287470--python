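"""Comparative analyses: variable-region trees and cross-assembly element comparison.

The tree over unit variable regions uses the 12 consensus-alignment columns
26-37 (1-based, the span that carries the type-defining motif), p-distances,
and neighbor joining with Newick output, so the topology can be re-estimated
externally with a likelihood method if desired. Cross-assembly comparisons
take an explicit element pairing (synteny discovery is out of scope) and
report lengths, global-alignment identity, and gap bases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .segmentation import UnitAlignment, make_aligner

PHYLO_START = 26  # 1-based inclusive consensus column range
PHYLO_END = 37


def extract_phylo_region(
    aln: UnitAlignment, start: int = PHYLO_START, end: int = PHYLO_END
) -> list[str]:
    """Per-unit subsequences over consensus columns ``start``..``end`` (1-based).

    Units are read off the alignment's match (consensus-coordinate) columns;
    gap characters are retained so the regions stay aligned.
    """
    cols = aln.match_columns()
    if len(cols) < end:
        raise ValueError(
            f"consensus has {len(cols)} columns; need at least {end}"
        )
    picked = cols[start - 1 : end]
    return ["".join(row[c] for c in picked) for row in aln.rows]


def p_distance(a: str, b: str) -> float:
    """Mismatch proportion over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError("p_distance needs equal-length gapped strings")
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x != y for x, y in pairs) / len(pairs)


def distance_matrix(seqs: list[str], ids: list[str]) -> DistanceMatrix:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[i], seqs[j])
    return DistanceMatrix(d, ids=ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; deterministic given the matrix.

    Negative branch lengths (possible for non-additive input) are clamped to
    zero. For fewer than 3 taxa a trivial tree is returned, splitting the
    pairwise distance evenly for n = 2.
    """
    ids = list(dm.ids)
    if len(ids) == 1:
        return TreeNode.read([f"{ids[0]}:0;"])
    if len(ids) == 2:
        half = dm[ids[0], ids[1]] / 2
        return TreeNode.read([f"({ids[0]}:{half},{ids[1]}:{half});"])
    tree = nj(dm, neg_as_zero=True)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


def compare_homologous_elements(
    elems_a: dict[str, str],
    elems_b: dict[str, str],
    pairing: list[tuple[str, str]],
) -> pd.DataFrame:
    """Length, identity and gap summary for explicitly paired elements.

    ``elems_a``/``elems_b`` map element id to sequence; ``pairing`` lists
    (id_a, id_b) homolog pairs. Identity is over aligned columns of a global
    alignment under the package's affine scheme; ``gap_bp`` is the total gap
    characters in that alignment (the machine-readable form of one homolog
    being shorter than the other).
    """
    aligner = make_aligner("global")
    rows = []
    for id_a, id_b in pairing:
        if id_a not in elems_a or id_b not in elems_b:
            raise KeyError(f"unpaired element id in ({id_a}, {id_b})")
        sa, sb = elems_a[id_a], elems_b[id_b]
        aln = aligner.align(sa, sb)[0]
        ga, gb = str(aln[0]), str(aln[1])
        matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
        rows.append(
            {
                "pair": f"{id_a}|{id_b}",
                "len_A": len(sa),
                "len_B": len(sb),
                "aligned_identity": matches / len(ga),
                "gap_bp": ga.count("-") + gb.count("-"),
            }
        )
    return pd.DataFrame(rows, columns=["pair", "len_A", "len_B", "aligned_identity", "gap_bp"])


def per_assembly_length_tally(
    annot_sets: dict[str, list], family: str
) -> pd.DataFrame:
    """Summed family bp per assembly, normalized by the grand total.

    Assemblies where the family is absent report 0 bp and a 0 share.
    """
    rows = []
    for assembly, annots in annot_sets.items():
        total = sum(a.end - a.start for a in annots if a.family == family)
        rows.append({"assembly": assembly, "total_bp": total})
    df = pd.DataFrame(rows, columns=["assembly", "total_bp"])
    grand = df["total_bp"].sum()
    df["normalized"] = df["total_bp"] / grand if grand else 0.0
    return df
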