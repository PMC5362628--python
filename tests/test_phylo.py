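"""p-distance, neighbor joining, bootstrap, and subgroup assignment."""

import itertools

import numpy as np
import pytest

from wrkykit.phylo import (
    DistanceMatrix,
    ReferencePanel,
    assign_subgroup,
    bootstrap_support,
    nj_tree,
    p_distance,
)
from wrkykit.synthetic_data import SUBGROUPS, make_proteome, make_reference_panel


# ---------------------------------------------------------------------------
# random additive trees (independent of the NJ implementation)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths.

    Returns (distance matrix over sorted labels, set of nontrivial splits).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # each cluster: (leaf set, {leaf: distance to cluster root})
    clusters = [({l}, {l: 0.0}) for l in labels]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        ba = rng.uniform(0.05, 1.0)
        bb = rng.uniform(0.05, 1.0)
        for la, va in da.items():
            for lb, vb in db.items():
                dist[frozenset((la, lb))] = va + ba + vb + bb
        merged = {l: v + ba for l, v in da.items()}
        merged.update({l: v + bb for l, v in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((sa | sb, merged))
    m = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            m[a, b] = m[b, a] = dist[frozenset((labels[a], labels[b]))]
    return DistanceMatrix(labels=labels, matrix=m)


def splits_from_distances(dm):
    """Four-point-condition splits: an independent read of the topology."""
    labels = dm.labels
    out = set()
    full = frozenset(labels)
    anchor = min(labels)
    for r in range(2, len(labels) - 1):
        for side in itertools.combinations(labels, r):
            side = frozenset(side)
            other = full - side
            ok = True
            for a, b in itertools.combinations(side, 2):
                for c, d in itertools.combinations(other, 2):
                    ab = dm.value(a, b) + dm.value(c, d)
                    ax = dm.value(a, c) + dm.value(b, d)
                    ay = dm.value(a, d) + dm.value(b, c)
                    if not (ab < ax - 1e-9 and abs(ax - ay) < 1e-6):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.add(side if anchor not in side else full - side)
    return out


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_definition_cases():
    dm = p_distance({"a": "AAAA", "b": "AAAA"})
    assert dm.value("a", "b") == 0.0
    dm = p_distance({"a": "AAAA", "b": "AATT"})
    assert dm.value("a", "b") == 0.5
    dm = p_distance({"a": "A-AA", "b": "AGAT"})
    assert dm.value("a", "b") == pytest.approx(1 / 3)


def test_p_distance_no_comparable_columns_raises():
    with pytest.raises(ValueError, match="x.*y|y.*x"):
        p_distance({"x": "A--", "y": "-AA", "z": "AAA"})


# ---------------------------------------------------------------------------
# NJ


def test_three_taxon_closed_form():
    m = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], matrix=m))
    realized = tree.path_length_matrix()
    assert np.allclose(realized.matrix, m)


def test_all_zero_matrix_gives_star():
    m = np.zeros((4, 4))
    tree = nj_tree(DistanceMatrix(labels=list("ABCD"), matrix=m))
    assert np.allclose(tree.path_length_matrix().matrix, 0.0)


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(labels=["A", "B"], matrix=np.zeros((2, 2))))


def test_nj_reconstructs_random_additive_matrices_exactly():
    rng = np.random.default_rng(101)
    for _ in range(40):
        n = int(rng.integers(5, 9))
        dm = random_additive_tree(rng, n)
        tree = nj_tree(dm)
        err = np.abs(tree.path_length_matrix().matrix - dm.matrix).max()
        assert err < 1e-9
        assert tree.splits() == splits_from_distances(dm)


def ls_best_quartet_split(dm):
    """Least-squares oracle over the 3 unrooted 4-taxon topologies."""
    a, b, c, d = dm.labels
    best = None
    for pair in ((a, b), (a, c), (a, d)):
        side = frozenset(pair)
        other = tuple(x for x in dm.labels if x not in side)
        p, q = tuple(side)
        r, s = other
        # edges: p, q, r, s pendant + internal; OLS design over 6 distances
        X = []
        y = []
        order = [p, q, r, s]
        for i in range(4):
            for j in range(i + 1, 4):
                u, v = order[i], order[j]
                row = [0.0] * 5
                row[i] = 1.0
                row[j] = 1.0
                crosses = (u in side) != (v in side)
                row[4] = 1.0 if crosses else 0.0
                X.append(row)
                y.append(dm.value(u, v))
        X = np.array(X)
        y = np.array(y)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = ((X @ coef - y) ** 2).sum()
        key = (resid, tuple(sorted(side)))
        if best is None or key < best[0:2]:
            best = (resid, tuple(sorted(side)), side)
    return best[2]


def test_four_taxon_topology_matches_least_squares_oracle():
    rng = np.random.default_rng(202)
    anchorless = 0
    for _ in range(30):
        dm = random_additive_tree(rng, 4)
        tree = nj_tree(dm)
        splits = tree.splits()
        assert len(splits) == 1
        got = next(iter(splits))
        want = ls_best_quartet_split(dm)
        full = frozenset(dm.labels)
        assert got in (want, full - want)


def test_label_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(303)
    dm = random_additive_tree(rng, 7)
    tree = nj_tree(dm)
    perm = rng.permutation(len(dm.labels))
    labels2 = [dm.labels[i] for i in perm]
    m2 = dm.matrix[np.ix_(perm, perm)]
    tree2 = nj_tree(DistanceMatrix(labels=labels2, matrix=m2))
    assert tree.splits() == tree2.splits()


def test_nj_agrees_with_dendropy_on_additive_matrix():
    import dendropy

    rng = np.random.default_rng(404)
    dm = random_additive_tree(rng, 6)
    tree = nj_tree(dm)
    csv_rows = ["," + ",".join(dm.labels)]
    for i, l in enumerate(dm.labels):
        csv_rows.append(l + "," + ",".join(str(x) for x in dm.matrix[i]))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=__import__("io").StringIO("\n".join(csv_rows)), delimiter=","
    )
    dtree = pdm.nj_tree()
    dtree.encode_bipartitions()
    full = frozenset(dm.labels)
    anchor = min(full)
    dsplits = set()
    for edge in dtree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
            continue
        side = frozenset(
            l.taxon.label for l in edge.head_node.leaf_iter()
        )
        if 2 <= len(side) <= len(full) - 2:
            dsplits.add(full - side if anchor in side else side)
    assert tree.splits() == dsplits


# ---------------------------------------------------------------------------
# bootstrap


STRONG_SIGNAL = {
    "A": "AAAAAAAACCCC",
    "B": "AAAAAAAACCCT",
    "C": "TTTTTTTTCCCC",
    "D": "TTTTTTTTCCCA",
}


def test_reps_zero_keeps_tree_unannotated():
    tree = bootstrap_support(STRONG_SIGNAL, reps=0)
    assert all(n.support is None for n in tree.internal_nodes())


def test_unanimous_signal_gives_full_support():
    seqs = {"A": "AAAA", "B": "AAAA", "C": "TTTT", "D": "TTTT"}
    tree = bootstrap_support(seqs, reps=50, seed=2)
    supports = [n.support for n in tree.internal_nodes() if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_newick_reproducible():
    t1 = bootstrap_support(STRONG_SIGNAL, reps=200, seed=5).newick(with_support=True)
    t2 = bootstrap_support(STRONG_SIGNAL, reps=200, seed=5).newick(with_support=True)
    assert t1 == t2


def test_supports_bounded_and_stable():
    t1 = bootstrap_support(STRONG_SIGNAL, reps=400, seed=1)
    t2 = bootstrap_support(STRONG_SIGNAL, reps=400, seed=99)
    s1 = {tuple(sorted(l.label for l in n.leaves())): n.support
          for n in t1.internal_nodes() if n.support is not None}
    s2 = {tuple(sorted(l.label for l in n.leaves())): n.support
          for n in t2.internal_nodes() if n.support is not None}
    for k, v in s1.items():
        assert 0.0 <= v <= 100.0
        assert abs(v - s2[k]) <= 5.0


# ---------------------------------------------------------------------------
# subgroup assignment


def test_query_identical_to_reference_gets_its_tag():
    panel = make_reference_panel(seed=2, n_per_tag=2)
    label = next(l for l, t in panel.tags.items() if t == "2b")
    tag, method = assign_subgroup(panel.sequences[label] , panel, query_group="2")
    assert tag == "2b"


def test_zero_noise_queries_all_correct():
    panel = make_reference_panel(seed=5, n_per_tag=3)
    queries = make_proteome({t: 2 for t in SUBGROUPS}, seed=55, flank_mut_rate=0.0)
    for _, row in queries.truth.iterrows():
        tag, _ = assign_subgroup(row["domain_seq"], panel)
        assert tag == row["subgroup"]


def test_non_group2_query_rejected():
    panel = make_reference_panel(seed=2, n_per_tag=2)
    with pytest.raises(ValueError):
        assign_subgroup("A" * 90, panel, query_group="3")


def test_equidistant_query_uses_deterministic_fallback():
    # two tags, query equally far from everything: falls back to the
    # lexicographically smallest nearest reference
    seqs = {"a1": "AAAA", "a2": "AAAT", "b1": "TTTT", "b2": "TTTA"}
    tags = {"a1": "2a", "a2": "2a", "b1": "2b", "b2": "2b"}
    panel = ReferencePanel(sequences=seqs, tags=tags)
    tag, method = assign_subgroup("ATAT", panel)
    tag2, _ = assign_subgroup("ATAT", panel)
    assert tag == tag2  # deterministic

def test_panel_requires_two_per_tag():
    with pytest.raises(ValueError):
        ReferencePanel(sequences={"a": "AA", "b": "AT"}, tags={"a": "2a", "b": "2b"})
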