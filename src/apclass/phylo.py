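"""Entropy-based alignment trimming, neighbor-joining trees and clade calls.

The classification consumes clade membership relative to anchor genes, not
likelihoods, so the in-repo tree builder is neighbor joining over simple
protein distances (p-distance or Poisson-corrected), with nonparametric
bootstrap over trimmed alignment columns.  Externally computed Newick trees
can be supplied instead wherever a tree is accepted.

Trimming is an entropy filter in the BMGE spirit: per-column Shannon entropy
of non-gap residues, normalized by log2(20) to [0, 1], with an additional
gap-fraction cutoff.  The full BMGE similarity-matrix smoothing is not
reproduced.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "TrimmedAlignment",
    "column_entropy",
    "column_gap_fraction",
    "entropy_trim",
    "distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "clade_assign",
    "leaf_bipartitions",
    "write_newick",
    "read_newick",
]

GAP_CHARS = {"-", ".", "*"}
MAX_ENTROPY = math.log2(20.0)
DEFAULT_ENTROPY_CUTOFF = 0.8  # middle of the published 0.7-0.9 window
DEFAULT_MAX_GAP_FRACTION = 0.2
NEWICK_KWARGS = dict(suppress_rooting=True, unquoted_underscores=True)


@dataclass
class TrimmedAlignment:
    """Kept-column view of an input MSA plus per-input-column entropies."""

    kept_columns: list[int]          # 0-based indices into the input MSA
    sequences: dict[str, str]        # trimmed aligned strings
    entropy: np.ndarray              # normalized entropy per input column

    def __post_init__(self) -> None:
        cols = self.kept_columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("kept_columns must be strictly increasing")
        if len({len(s) for s in self.sequences.values()}) > 1:
            raise ValueError("trimmed sequences must share one length")

    @property
    def n_columns(self) -> int:
        return len(self.kept_columns)


def _column(msa: dict[str, str], column: int) -> list[str]:
    return [seq[column].upper() for seq in msa.values()]


def column_entropy(msa: dict[str, str], column: int) -> float:
    """Shannon entropy of the column's non-gap residues, normalized by
    log2(20).  All-gap columns are defined as entropy 1 (removable)."""
    residues = [r for r in _column(msa, column) if r not in GAP_CHARS]
    if not residues:
        return 1.0
    counts = Counter(residues)
    total = len(residues)
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return min(h / MAX_ENTROPY, 1.0)


def column_gap_fraction(msa: dict[str, str], column: int) -> float:
    col = _column(msa, column)
    return sum(1 for r in col if r in GAP_CHARS) / len(col)


def entropy_trim(msa: dict[str, str],
                 cutoff: float = DEFAULT_ENTROPY_CUTOFF,
                 max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
                 ) -> TrimmedAlignment:
    """Drop columns with normalized entropy > cutoff or too many gaps."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(next(iter(msa.values())))
    if len({len(s) for s in msa.values()}) != 1:
        raise ValueError("aligned sequences must share one length")
    entropies = np.array([column_entropy(msa, j) for j in range(width)])
    kept = [j for j in range(width)
            if entropies[j] <= cutoff and column_gap_fraction(msa, j) <= max_gap_fraction]
    if not kept:
        raise ValueError(
            "all columns were trimmed; raise the entropy cutoff or gap fraction")
    sequences = {sid: "".join(seq[j] for j in kept) for sid, seq in msa.items()}
    return TrimmedAlignment(kept_columns=kept, sequences=sequences,
                            entropy=entropies)


def distance_matrix(alignment: TrimmedAlignment | dict[str, str],
                    model: str = "poisson") -> tuple[list[str], np.ndarray]:
    """Pairwise distances with pairwise deletion of gap sites.

    ``p-distance`` is the mismatch fraction; ``poisson`` applies
    d = -ln(1 - p).  A pair with no comparable sites is an error.
    """
    msa = alignment.sequences if isinstance(alignment, TrimmedAlignment) else alignment
    labels = list(msa)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    seqs = [msa[l].upper() for l in labels]
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(f"no comparable sites between "
                                 f"{labels[i]!r} and {labels[j]!r}")
            p = mismatch / comparable
            if model == "p-distance":
                d = p
            elif model == "poisson":
                d = -math.log(1.0 - min(p, 0.95))  # saturation guard
            else:
                raise ValueError(f"unknown distance model {model!r}")
            dist[i, j] = dist[j, i] = d
    return labels, dist


def nj_tree(dist: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-matrix minimum ties resolve to the smallest active (i, j) index pair;
    negative branch-length estimates are clamped to zero.  The returned tree
    is unrooted (trifurcating seed node).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("distance matrix must be square with n >= 3")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = {i: dendropy.Node(taxon=tns.get_taxon(labels[i])) for i in range(n)}
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def join(i, j, li, lj):
        nonlocal next_id
        parent = dendropy.Node()
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = max(0.0, li)
        child_j.edge.length = max(0.0, lj)
        nodes[next_id] = parent
        next_id += 1
        return next_id - 1

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        dij = D[(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = join(i, j, li, lj)
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
            D[(u, k)] = D[(k, u)] = max(0.0, duk)
        D[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[(i, j)] + D[(i, k)] - D[(j, k)])
        lj = 0.5 * (D[(i, j)] + D[(j, k)] - D[(i, k)])
        lk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
        root = dendropy.Node()
        for idx, length in ((i, li), (j, lj), (k, lk)):
            child = nodes.pop(idx)
            root.add_child(child)
            child.edge.length = max(0.0, length)
        tree.seed_node = root
    else:  # exactly 2 remain (possible when starting from n = 3 after one join)
        i, j = active
        root = dendropy.Node()
        for idx in (i, j):
            child = nodes.pop(idx)
            root.add_child(child)
            child.edge.length = max(0.0, D[(i, j)] / 2.0)
        tree.seed_node = root
    tree.is_rooted = False
    return tree


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-name sets.

    Each internal edge splits the leaves; the side not containing the
    lexicographically smallest leaf is the canonical representative.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        if ref in side:
            side = all_leaves - side
        bips.add(side)
    return bips


def bootstrap_supports(trimmed: TrimmedAlignment, n_replicates: int = 100,
                       seed: int = 0, model: str = "poisson") -> dendropy.Tree:
    """Point-estimate NJ tree with bootstrap supports on internal nodes.

    Columns of the trimmed alignment are resampled with replacement;
    support is the fraction of replicate trees containing each bipartition
    of the point tree, written as the internal node label.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, d = distance_matrix(trimmed, model=model)
    tree = nj_tree(d, labels)
    point_bips = leaf_bipartitions(tree)
    counts = {bip: 0 for bip in point_bips}
    rng = np.random.default_rng(seed)
    ids = list(trimmed.sequences)
    cols = [[s[j] for s in trimmed.sequences.values()]
            for j in range(trimmed.n_columns)]
    for _ in range(n_replicates):
        pick = rng.integers(0, trimmed.n_columns, size=trimmed.n_columns)
        rep = {sid: "".join(cols[j][k] for j in pick)
               for k, sid in enumerate(ids)}
        try:
            rep_labels, rep_d = distance_matrix(rep, model=model)
        except ValueError:  # a replicate can hit all-gap pairs
            continue
        rep_bips = leaf_bipartitions(nj_tree(rep_d, rep_labels))
        for bip in point_bips:
            if bip in rep_bips:
                counts[bip] += 1

    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            continue
        if ref in side:
            side = all_leaves - side
        node.label = f"{counts.get(side, 0) / n_replicates:.2f}"
    return tree


def clade_assign(tree: dendropy.Tree,
                 anchors: dict[str, str]) -> dict[str, str]:
    """Label every leaf by its anchor neighborhood on the tree.

    Each non-anchor leaf is assigned the group of its nearest anchor by
    patristic (path-length) distance, i.e. the group whose anchor clade it
    falls closest to; a leaf whose two best groups are equidistant (within
    a 1e-6 relative tolerance) is ``unassigned``.  Anchor leaves always
    keep their own label.  On a tree where every group's anchors sit in a
    clean clade this labels every leaf with its clade's group.
    """
    leaf_names = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = [a for a in anchors if a not in leaf_names]
    if missing:
        raise ValueError(f"anchor leaves missing from tree: {missing}")
    groups: dict[str, list[str]] = {}
    for leaf, group in anchors.items():
        groups.setdefault(group, []).append(leaf)

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace
            if t.label in leaf_names}
    assignment: dict[str, str] = {}
    for leaf in sorted(leaf_names):
        if leaf in anchors:
            assignment[leaf] = anchors[leaf]
            continue
        dists = []
        for group, anchor_leaves in groups.items():
            d = min(pdm.patristic_distance(taxa[leaf], taxa[a])
                    for a in anchor_leaves)
            dists.append((d, group))
        dists.sort()
        if len(dists) > 1:
            best, second = dists[0][0], dists[1][0]
            scale = max(abs(best), abs(second), 1e-12)
            if (second - best) / scale < 1e-6:
                assignment[leaf] = "unassigned"
                continue
        assignment[leaf] = dists[0][1]
    return assignment


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Deterministic Newick serialization (supports as internal labels)."""
    text = tree.as_string(schema="newick", **NEWICK_KWARGS)
    if path is not None:
        from pathlib import Path
        Path(path).write_text(text)
    return text


def read_newick(source) -> dendropy.Tree:
    """Parse Newick text or a file path."""
    from pathlib import Path
    try:
        is_file = Path(source).exists()
    except OSError:
        is_file = False
    if is_file:
        return dendropy.Tree.get(path=str(source), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=source, schema="newick",
                             preserve_underscores=True)
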