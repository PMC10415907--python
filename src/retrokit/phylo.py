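"""Distance phylogenetics: column filtering, distances, NJ, bootstrap.

The tree-building surrogate used throughout the family analysis: a 95%
partial-deletion column filter, simple distance models (p-distance,
Poisson correction for proteins, Jukes-Cantor for DNA), canonical
Saitou-Nei neighbor-joining with deterministic tie-breaks, and
nonparametric bootstrap supports on the internal bipartitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from .seqio import GAP, Msa, SequenceRecord

AMBIGUOUS = {"dna": {"N"}, "protein": {"X"}}

DEFAULT_MAX_DISTANCE = 10.0  # cap for saturated pairs


def _is_missing(ch: str, alphabet: str) -> bool:
    return ch == GAP or ch in AMBIGUOUS.get(alphabet, set())


def partial_deletion_filter(msa: Msa, min_coverage: float = 0.95) -> Msa:
    """Remove alignment columns with insufficient site coverage.

    A column is retained exactly when the fraction of rows carrying a real
    residue (not a gap, not an ambiguity character) is >= ``min_coverage``
    (the boundary case counts as covered). Row order is preserved;
    idempotent by construction.
    """
    keep = []
    for i in range(msa.n_cols):
        col = msa.column(i)
        good = sum(1 for c in col if not _is_missing(c, msa.alphabet))
        if good / msa.n_rows >= min_coverage:
            keep.append(i)
    if not keep:
        raise ValueError("partial-deletion filter removed every column")
    records = [
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[i] for i in keep),
            description=r.description,
        )
        for r in msa.records
    ]
    return Msa(records=records, alphabet=msa.alphabet)


@dataclass
class DistanceMatrix:
    taxa: List[str]
    d: np.ndarray
    saturated: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix has a nonzero diagonal")


def distance_matrix(
    msa: Msa, model: str = "p", max_distance: float = DEFAULT_MAX_DISTANCE
) -> DistanceMatrix:
    """Pairwise distances with per-pair complete deletion of missing columns.

    Models: ``p`` (proportion of differing sites), ``poisson``
    (-ln(1 - p), protein), ``jc69`` (-(3/4) ln(1 - 4p/3), DNA). Pairs
    whose correction diverges are capped at ``max_distance`` and flagged.
    """
    if model not in ("p", "poisson", "jc69"):
        raise ValueError(f"unknown distance model {model!r}")
    if msa.n_rows < 3:
        raise ValueError("need at least 3 sequences")
    taxa = [r.id for r in msa.records]
    arr = np.array(
        [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in msa.records]
    )
    missing_chars = {GAP} | AMBIGUOUS.get(msa.alphabet, set())
    missing = np.isin(arr, [ord(c) for c in missing_chars])
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            valid = int(ok.sum())
            diff = int(((arr[i] != arr[j]) & ok).sum())
            if valid == 0:
                raise ValueError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}"
                )
            p = diff / valid
            if model == "p":
                dist = p
            elif model == "poisson":
                arg = 1.0 - p
                dist = -math.log(arg) if arg > 0 else None
            else:
                arg = 1.0 - 4.0 * p / 3.0
                dist = -0.75 * math.log(arg) if arg > 0 else None
            if dist is None or dist > max_distance:
                dist = max_distance
                saturated.append((taxa[i], taxa[j]))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, d=d, saturated=saturated)


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei neighbor-joining.

    Iteratively joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties break on the lexicographically smallest (smallest member leaf
    label) pair. Branch lengths follow the standard formulas; negative
    estimates are clamped to zero and recorded in the tree's
    ``clamped_edges`` annotation. The result is an unrooted tree
    represented with a trifurcating seed node (for >= 4 taxa).
    """
    n0 = len(D.taxa)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    ns = dendropy.TaxonNamespace(D.taxa)
    nodes = []
    for label in D.taxa:
        node = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(node)
    labels = list(D.taxa)  # per-cluster smallest leaf label, for tie-breaks
    d = D.d.astype(float).copy()
    active = list(range(n0))
    clamped = []

    def _join(i: int, j: int, li: float, lj: float) -> int:
        nonlocal d, labels, nodes
        parent = dendropy.Node()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            if ln < 0:
                clamped.append(child)
                ln = 0.0
            child.edge.length = ln
            parent.add_child(child)
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                la, lb = labels[active[a]], labels[active[b]]
                key = (q, min(la, lb), max(la, lb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        k = _join(i, j, li, lj)
        # distances from the new node to every other active cluster
        newrow = np.zeros(len(nodes))
        for c in range(m):
            o = active[c]
            if o in (i, j):
                continue
            newrow[o] = 0.5 * (d[i, o] + d[j, o] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, : k] = newrow[:k]
        d[: k, k] = newrow[:k]
        active = [o for o in active if o not in (i, j)] + [k]

    tree = dendropy.Tree(taxon_namespace=ns)
    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, v in ((i, vi), (j, vj), (k, vk)):
            if v < 0:
                clamped.append(nodes[idx])
                v = 0.0
            nodes[idx].edge.length = v
            tree.seed_node.add_child(nodes[idx])
    tree.clamped_edges = len(clamped)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels.

    Each internal edge contributes the side not containing the
    alphabetically first taxon, so the representation is rotation- and
    rooting-invariant.
    """
    leaves = sorted(t.label for t in tree.taxon_namespace)
    all_set = frozenset(leaves)
    ref = leaves[0]
    out: Set[FrozenSet[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    msa: Msa,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "poisson",
    min_coverage: float = 0.95,
    apply_filter: bool = True,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    The alignment is column-filtered once, the tree is built on it, then
    ``replicates`` resampled alignments (columns drawn with replacement)
    are rebuilt and each original internal bipartition's support is the
    percentage of replicates containing it, rounded to an integer and
    stored as the internal node label. Bit-reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if msa.n_rows < 4:
        raise ValueError("bootstrap supports need at least 4 sequences")
    work = partial_deletion_filter(msa, min_coverage) if apply_filter else msa
    tree = nj_tree(distance_matrix(work, model))
    target = tree_bipartitions(tree)
    counts: Dict[FrozenSet[str], int] = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    cols = np.arange(work.n_cols)
    mat = np.array([list(r.residues) for r in work.records])
    for _ in range(replicates):
        pick = rng.choice(cols, size=work.n_cols, replace=True)
        rep = Msa(
            records=[
                SequenceRecord(id=r.id, residues="".join(row))
                for r, row in zip(work.records, mat[:, pick])
            ],
            alphabet=work.alphabet,
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue
        for bp in tree_bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    ref = sorted(t.label for t in tree.taxon_namespace)[0]
    all_set = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if side in counts:
            node.label = str(round(100 * counts[side] / replicates))
    return tree


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance via bipartition symmetric difference."""
    ba, bb = tree_bipartitions(tree_a), tree_bipartitions(tree_b)
    return len(ba ^ bb)
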