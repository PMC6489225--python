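"""Distance-based phylogenetics: p-distances, neighbor-joining, bootstrap.

Implements the Saitou–Nei neighbor-joining algorithm on uncorrected pairwise
p-distances (Poisson correction optional) and annotates internal edges of the
full-data tree with bootstrap support from column resampling. p-distance is
not guaranteed to satisfy the triangle inequality; NJ does not require it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MISSING = {ord("-"), ord("X")}


@dataclass
class Alignment:
    """A multiple sequence alignment over amino acids plus '-' (gap) and 'X'."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        if len(self.ids) < 2:
            raise ValidationError("alignment needs >= 2 taxa")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate taxon labels")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.seqs).encode("ascii"),
                             dtype=np.uint8).reshape(self.n_taxa, self.n_columns)

    def take_columns(self, idx: np.ndarray) -> "Alignment":
        arr = self.to_array()[:, idx]
        return Alignment(list(self.ids),
                         [row.tobytes().decode("ascii") for row in arr])


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite distances")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("asymmetric distance matrix")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances")


def pairwise_pdistance(aln: Alignment, gap_mode: str = "pairwise_deletion",
                       correction: str = "p") -> DistanceMatrix:
    """Pairwise p-distance (mismatch proportion) over comparable columns.

    ``pairwise_deletion`` compares, per pair, the columns where both residues
    are non-gap and non-X; ``complete_deletion`` restricts every pair to the
    columns with no gap/X in any taxon. ``correction='poisson'`` applies the
    multiple-hit correction d = -ln(1 - p).
    """
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise ValidationError(f"unknown gap_mode {gap_mode!r}")
    if correction not in ("p", "poisson"):
        raise ValidationError(f"unknown correction {correction!r}")
    arr = aln.to_array()
    ok = ~np.isin(arr, list(MISSING))
    if gap_mode == "complete_deletion":
        keep = ok.all(axis=0)
        if not keep.any():
            raise ValidationError("no columns free of gaps/X under complete deletion")
        arr, ok = arr[:, keep], ok[:, keep]
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable columns for pair ({aln.ids[i]}, {aln.ids[j]})")
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValidationError(
                        f"p-distance 1.0 for ({aln.ids[i]}, {aln.ids[j]}): "
                        "Poisson correction undefined")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted representation of an unrooted tree."""

    __slots__ = ("name", "children", "support", "_min_leaf")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[list[tuple["TreeNode", float]]] = None):
        self.name = name
        self.children: list[tuple[TreeNode, float]] = children or []
        self.support: Optional[int] = None
        # smallest leaf label under this node; used for deterministic tie-breaks
        self._min_leaf = name if name is not None else min(
            c._min_leaf for c, _ in self.children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c, _ in self.children for l in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree presented with a (tri- or multi-furcating) root node.

    Internal nodes may carry integer bootstrap support (0-100); branch
    lengths are non-negative after clamping.
    """

    root: TreeNode
    n_bootstrap_completed: Optional[int] = None

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def to_newick(self) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = "" if node.support is None else str(node.support)
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6g}"
        return fmt(self.root, None) + ";"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial leaf bipartitions keyed by their canonical side.

        The canonical side is the one not containing the lexicographically
        smallest leaf, so keys are comparable across differently rooted
        representations of the same unrooted tree.
        """
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(l.name for l in child.leaves())
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out[side] = child
                walk(child)
        walk(self.root)
        return out

    def path_length_matrix(self, labels: Optional[Sequence[str]] = None) -> np.ndarray:
        """Leaf-to-leaf path lengths (sum of branch lengths), in label order."""
        labels = list(labels) if labels is not None else sorted(self.leaf_names)
        idx = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))

        def depths(node: TreeNode, d: float) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: d}
            out = {}
            for c, bl in node.children:
                out.update(depths(c, d + bl))
            return out

        def walk(node: TreeNode):
            # paths through this node between different child subtrees
            sides = [depths(c, bl) for c, bl in node.children]
            for a in range(len(sides)):
                for b in range(a + 1, len(sides)):
                    for la, da in sides[a].items():
                        for lb, db in sides[b].items():
                            dist[idx[la], idx[lb]] = dist[idx[lb], idx[la]] = da + db
            for c, _ in node.children:
                walk(c)
        walk(self.root)
        return dist


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor-joining.

    Iteratively joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    branch lengths from the rate-corrected split formula. A negative branch
    length is clamped to zero with the deficit moved to its sister edge (the
    pair's total split distance is preserved). Ties on Q are broken by the
    smallest (sorted) pair of subtree leaf labels, so the result is invariant
    to input row order up to relabelling.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    D = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((tuple(sorted((nodes[a]._min_leaf, nodes[b]._min_leaf))), (a, b))
                   for a, b in ties if a < b)[1]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            lj, li = 0.0, d_ij
        new_node = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)], new_row[keep]]),
                       np.append(new_row[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [new_node]

    # resolve the final three nodes onto the unrooted trifurcation
    (a, b, c), d = nodes, D
    la = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    return PhyloTree(TreeNode(children=[(a, la), (b, lb), (c, lc)]))


def bootstrap_support(aln: Alignment, n_replicates: int = 1000, seed: int = 0,
                      gap_mode: str = "pairwise_deletion",
                      correction: str = "p") -> PhyloTree:
    """NJ tree from the full alignment, internal edges annotated with the
    percentage of column-resampled replicates containing the same bipartition.

    Replicates whose resampled columns leave some pair with no comparable
    column are skipped with a warning; the support denominator is the number
    of completed replicates.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    tree = neighbor_joining(pairwise_pdistance(aln, gap_mode, correction))
    biparts = tree.bipartitions()
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    completed = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep_aln = aln.take_columns(cols)
        try:
            rep_tree = neighbor_joining(pairwise_pdistance(rep_aln, gap_mode, correction))
        except ValidationError as e:
            logger.warning("bootstrap replicate skipped: %s", e)
            continue
        completed += 1
        rep_biparts = rep_tree.bipartitions()
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    if completed == 0:
        raise ValidationError("all bootstrap replicates failed")
    for key, node in biparts.items():
        node.support = int(round(100.0 * counts[key] / completed))
    tree.n_bootstrap_completed = completed
    return tree
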