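"""Entropy trimming vs a per-column oracle, NJ vs additive ground truth and
scikit-bio, bootstrap supports and clade assignment."""

import math

import numpy as np
import pytest

from apclass.phylo import (bootstrap_supports, clade_assign, column_entropy,
                           column_gap_fraction, distance_matrix, entropy_trim,
                           leaf_bipartitions, nj_tree, read_newick,
                           write_newick)
from apclass.synth import SynthConfig, make_family

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_msa(n, width, seed, gap_rate=0.1):
    rng = np.random.default_rng(seed)
    msa = {}
    for i in range(n):
        chars = rng.choice(AA, size=width)
        gaps = rng.random(width) < gap_rate
        msa[f"s{i}"] = "".join("-" if g else c for c, g in zip(chars, gaps))
    return msa


# --- entropy ---------------------------------------------------------------

def test_conserved_column_has_zero_entropy():
    assert column_entropy({"a": "A", "b": "A", "c": "A", "d": "A"}, 0) == 0.0


def test_twenty_distinct_residues_have_entropy_one():
    msa = {f"s{i}": aa for i, aa in enumerate(AA)}
    assert column_entropy(msa, 0) == pytest.approx(1.0)


def test_mixed_column_closed_form():
    # residues A, A, C, D: p = (1/2, 1/4, 1/4)
    msa = {"a": "A", "b": "A", "c": "C", "d": "D"}
    expected = -(0.5 * math.log2(0.5) + 2 * 0.25 * math.log2(0.25)) / math.log2(20)
    assert column_entropy(msa, 0) == pytest.approx(expected)


def test_all_gap_column_is_removable():
    assert column_entropy({"a": "-", "b": "-"}, 0) == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_entropy_trim_equals_per_column_oracle(seed):
    msa = random_msa(8, 60, seed)
    cutoff, max_gap = 0.8, 0.25
    trimmed = entropy_trim(msa, cutoff=cutoff, max_gap_fraction=max_gap)
    expected = [j for j in range(60)
                if column_entropy(msa, j) <= cutoff
                and column_gap_fraction(msa, j) <= max_gap]
    assert trimmed.kept_columns == expected
    for sid in msa:
        assert trimmed.sequences[sid] == "".join(msa[sid][j] for j in expected)


def test_trim_keeps_everything_at_unit_cutoffs_and_is_idempotent():
    msa = random_msa(6, 40, 3)
    trimmed = entropy_trim(msa, cutoff=1.0, max_gap_fraction=1.0)
    assert trimmed.kept_columns == list(range(40))
    again = entropy_trim(trimmed.sequences, cutoff=1.0, max_gap_fraction=1.0)
    assert again.sequences == trimmed.sequences


def test_zero_cutoff_keeps_only_invariant_columns():
    msa = {"a": "AAC", "b": "ADC", "c": "AEC"}
    trimmed = entropy_trim(msa, cutoff=0.0, max_gap_fraction=1.0)
    assert trimmed.kept_columns == [0, 2]


def test_trimming_everything_raises():
    msa = {f"s{i}": aa for i, aa in enumerate(AA[:6])}
    with pytest.raises(ValueError, match="cutoff"):
        entropy_trim(msa, cutoff=0.0)


# --- distances -------------------------------------------------------------

def test_identical_sequences_give_zero_matrix():
    labels, d = distance_matrix({"a": "AAAA", "b": "AAAA", "c": "AAAA"},
                                model="p-distance")
    assert np.allclose(d, 0.0)


def test_p_distance_arithmetic():
    labels, d = distance_matrix({"a": "AAAA", "b": "AAAT", "c": "TTTT"},
                                model="p-distance")
    assert d[labels.index("a"), labels.index("b")] == pytest.approx(0.25)


def test_pairwise_deletion_recount():
    msa = {"a": "AC-DE", "b": "AC-DD", "c": "ACGDE", "d": "TTTTT"}
    labels, d = distance_matrix(msa, model="p-distance")
    # a vs b: 4 comparable sites, 1 mismatch
    assert d[labels.index("a"), labels.index("b")] == pytest.approx(0.25)
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)


def test_incomparable_pair_raises_with_names():
    msa = {"a": "AA--", "b": "--AA", "c": "AAAA"}
    with pytest.raises(ValueError, match="'a' and 'b'"):
        distance_matrix(msa, model="p-distance")


# --- neighbor joining ------------------------------------------------------

def random_additive_tree(n_leaves, rng):
    """Random binary tree; returns (children maps, leaf names, distances)."""
    nodes = [(f"L{i}",) for i in range(n_leaves)]
    lengths = {}
    children = {}
    counter = [0]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = (f"N{counter[0]}",)
        counter[0] += 1
        children[parent] = (nodes[i], nodes[j])
        lengths[nodes[i]] = float(rng.uniform(0.1, 1.0))
        lengths[nodes[j]] = float(rng.uniform(0.1, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]

    leaf_paths = {}

    def walk(node, path):
        if node not in children:
            leaf_paths[node[0]] = path
            return
        for child in children[node]:
            walk(child, path + [(child)])

    walk(root, [])
    names = sorted(leaf_paths)
    n = len(names)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            pa, pb = leaf_paths[names[a]], leaf_paths[names[b]]
            shared = 0
            for x, y in zip(pa, pb):
                if x == y:
                    shared += 1
                else:
                    break
            dist = sum(lengths[e] for e in pa[shared:]) + \
                sum(lengths[e] for e in pb[shared:])
            d[a, b] = d[b, a] = dist
    bips = set()
    all_names = frozenset(names)
    ref = min(names)

    def leafset(node):
        if node not in children:
            return frozenset([node[0]])
        a, b = children[node]
        return leafset(a) | leafset(b)

    for node in children:
        s = leafset(node)
        if 1 < len(s) < n - 1:
            bips.add(all_names - s if ref in s else s)
    return names, d, bips


@pytest.mark.parametrize("seed", range(100))
def test_nj_recovers_random_additive_eight_taxon_trees(seed):
    rng = np.random.default_rng(seed)
    names, d, true_bips = random_additive_tree(8, rng)
    tree = nj_tree(d, names)
    assert leaf_bipartitions(tree) == true_bips


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = nj_tree(d, ["a", "b", "c"])
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    # three-point formulas: la=(dab+dac-dbc)/2 etc.
    assert lengths["a"] == pytest.approx(2.0)
    assert lengths["b"] == pytest.approx(3.0)
    assert lengths["c"] == pytest.approx(7.0)


def test_nj_agrees_with_scikit_bio_on_family_distances():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    fam = make_family(SynthConfig(seed=7, n_genes=16))
    labels, d = distance_matrix(fam["sequences"])
    mine = leaf_bipartitions(nj_tree(d, labels))
    sk = skbio_nj(DistanceMatrix(d, labels))
    names = frozenset(labels)
    ref = min(names)
    theirs = set()
    for node in sk.non_tips():
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(names) - 1:
            theirs.add(frozenset(names - s) if ref in s else s)
    assert mine == theirs


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1], [1, 0]], float), ["a", "b"])
    bad = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
    with pytest.raises(ValueError):
        nj_tree(bad, ["a", "b", "c"])


def test_nj_branch_lengths_never_negative():
    rng = np.random.default_rng(9)
    labels, d = distance_matrix(random_msa(8, 50, 9, gap_rate=0.0))
    tree = nj_tree(d, labels)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0.0


# --- newick / bootstrap / clades -------------------------------------------

def test_newick_round_trip_is_byte_identical():
    fam = make_family(SynthConfig(seed=5, n_genes=12))
    labels, d = distance_matrix(fam["sequences"])
    text1 = write_newick(nj_tree(d, labels))
    text2 = write_newick(read_newick(text1))
    assert text1 == text2


def test_bootstrap_supports_separate_clean_clades():
    fam = make_family(SynthConfig(seed=42, n_genes=16))
    trimmed = entropy_trim(fam["sequences"], cutoff=1.0, max_gap_fraction=1.0)
    tree = bootstrap_supports(trimmed, n_replicates=40, seed=42)
    # the deepest split (group IV vs rest) must be near-unanimous
    bips = {frozenset(l.taxon.label for l in n.leaf_iter()): n.label
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node and n.label}
    group_iv = frozenset(l for l, g in fam["labels"].items() if g == "IV")
    matching = [float(v) for k, v in bips.items()
                if k == group_iv or k == frozenset(fam["labels"]) - group_iv]
    assert matching and max(matching) >= 0.95


def test_single_replicate_supports_are_binary():
    fam = make_family(SynthConfig(seed=6, n_genes=10))
    trimmed = entropy_trim(fam["sequences"], cutoff=1.0, max_gap_fraction=1.0)
    tree = bootstrap_supports(trimmed, n_replicates=1, seed=0)
    values = {n.label for n in tree.preorder_node_iter()
              if not n.is_leaf() and n.label}
    assert values <= {"0.00", "1.00"}


def test_clade_assignment_recovers_simulated_groups():
    fam = make_family(SynthConfig(seed=42, n_genes=50))
    labels, d = distance_matrix(fam["sequences"])
    assignment = clade_assign(nj_tree(d, labels), fam["anchors"])
    non_anchor = [l for l in assignment if l not in fam["anchors"]]
    acc = sum(assignment[l] == fam["labels"][l] for l in non_anchor) / len(non_anchor)
    assert acc >= 0.95


def test_missing_anchor_raises():
    fam = make_family(SynthConfig(seed=3, n_genes=10))
    labels, d = distance_matrix(fam["sequences"])
    tree = nj_tree(d, labels)
    with pytest.raises(ValueError, match="anchor"):
        clade_assign(tree, {"ghost_leaf": "I"})


def test_leaf_between_two_anchor_clades_is_unassigned():
    # two tight pairs plus one leaf equidistant from both pairs
    newick = "((a1:0.1,a2:0.1):1.0,(b1:0.1,b2:0.1):1.0,mid:1.0);"
    tree = read_newick(newick)
    assignment = clade_assign(tree, {"a1": "A", "a2": "A",
                                     "b1": "B", "b2": "B"})
    assert assignment["mid"] == "unassigned"
    assert assignment["a1"] == "A" and assignment["b2"] == "B"
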