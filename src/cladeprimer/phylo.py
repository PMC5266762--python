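"""Distance-based phylogenetics for amplicon sets.

Pairwise identity on an alignment, Jukes-Cantor correction of p-distances,
and a deterministic Saitou-Nei neighbor-joining implementation producing
scikit-bio :class:`~skbio.TreeNode` trees (and hence Newick).

Identity/p-distance convention: a position counts as a match iff both
symbols are concrete (A/C/G/T) and equal; columns with a gap or an ambiguity
code in either row are excluded from the comparison. This is conservative
and reproducible across tools.

Neighbor joining follows the standard Q-criterion agglomeration. Ties in Q
are broken by the smallest (i, j) index pair; negative branch lengths are
clamped to zero with the deficit transferred to the sibling edge, so path
lengths through the joined pair are preserved and the Newick output is valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import io as _io

__all__ = [
    "AlignedSet",
    "SaturationError",
    "read_alignment",
    "percent_identity",
    "p_distance",
    "jc_distance",
    "jc_expected_p",
    "distance_matrix",
    "neighbor_joining",
    "bipartitions",
    "same_topology",
    "to_newick",
    "write_distance_matrix",
]

_CONCRETE = frozenset(b"ACGT")


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor saturation limit of 3/4."""


@dataclass
class AlignedSet:
    """Equal-length gapped sequences with ids (alphabet: IUPAC plus '-')."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("aligned sequences must all have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0


def read_alignment(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA ('.' and '-' both accepted as gaps)."""
    records = _io.read_fasta(path, allow_gaps=True)
    return AlignedSet(
        ids=[r.id for r in records],
        seqs=[r.seq.replace(".", "-") for r in records],
    )


def _comparable(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    concrete = np.frombuffer(b"ACGT", dtype=np.uint8)
    mask = np.isin(aa, concrete) & np.isin(bb, concrete)
    return aa, bb, mask


def percent_identity(a: str, b: str) -> float:
    """100 x matches / compared positions; gap/ambiguity columns excluded."""
    aa, bb, mask = _comparable(a, b)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable (both-concrete) positions")
    return 100.0 * int((aa[mask] == bb[mask]).sum()) / n


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over comparable positions."""
    return 1.0 - percent_identity(a, b) / 100.0


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3), for 0 <= p < 3/4."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(
            f"p={p} outside [0, 0.75); Jukes-Cantor distance undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites after d substitutions/site: (3/4)(1 - e^(-4d/3))."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def distance_matrix(aln: AlignedSet, correction: str = "jc") -> DistanceMatrix:
    """All-pairs distance matrix ('jc' corrected or raw 'p')."""
    if correction not in ("jc", "p"):
        raise ValueError("correction must be 'jc' or 'p'")
    n = len(aln)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.seqs[i], aln.seqs[j])
            D[i, j] = D[j, i] = jc_distance(p) if correction == "jc" else p
    return DistanceMatrix(D, ids=aln.ids)


def _clamped_pair(li: float, lj: float) -> tuple[float, float]:
    # clamp a negative edge to 0, moving the deficit to the sibling so the
    # pair's summed length is preserved
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix | np.ndarray,
                     ids: Sequence[str] | None = None) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    Deterministic: Q-ties broken by the smallest (i, j) pair in current
    matrix order; negative branch lengths clamped as documented above.
    """
    if isinstance(dm, DistanceMatrix):
        D = dm.data.astype(float).copy()
        taxa = list(dm.ids)
    else:
        D = np.asarray(dm, dtype=float).copy()
        if ids is None:
            raise ValueError("ids required when passing a bare array")
        taxa = list(ids)
    n = D.shape[0]
    if D.shape != (n, n) or len(taxa) != n:
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = smallest (i, j) among ties
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamped_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        d_new = d_new[keep]
        new_i = keep.index(i)
        D[new_i, :] = d_new
        D[:, new_i] = d_new
        D[new_i, new_i] = 0.0
        nodes = [parent if k == i else nodes[k] for k in keep]

    # resolve the final three nodes around one internal vertex (three-point formulas)
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of an (un)rooted tree as unordered pairs of leaf-name sets."""
    leaves = frozenset(leaf.name for leaf in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({side, leaves - side}))
    return splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True iff the two trees induce identical unrooted splits on the same leaves."""
    l1 = frozenset(x.name for x in t1.tips())
    l2 = frozenset(x.name for x in t2.tips())
    return l1 == l2 and bipartitions(t1) == bipartitions(t2)


def to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-style square matrix as TSV (taxa on rows and columns)."""
    import pandas as pd

    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
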