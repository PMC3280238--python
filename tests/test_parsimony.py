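"""Parsimony: exhaustive-enumeration oracles for Fitch scoring and tree
search, plus bootstrap/consensus/rooting behaviour."""

import itertools

import numpy as np
import pytest

from natx import parsimony as P
from natx.align import CharacterMatrix
from natx.tree import parse_newick

# ---------------------------------------------------------------------------
# oracle helpers: enumerate all unrooted topologies and score by brute force


def canon(members, names):
    """Canonical bipartition key: the side excluding the smallest leaf."""
    members = frozenset(members)
    names = set(names)
    return frozenset(names - members) if min(names) in members else members


def all_topologies(labels):
    """All unrooted binary topologies as newick strings rooted at labels[0]."""
    assert len(labels) >= 3

    def insert(tree, lab):
        yield (tree, lab)
        if isinstance(tree, tuple) and len(tree) == 2:
            left, right = tree
            for sub in insert(left, lab):
                yield (sub, right)
            for sub in insert(right, lab):
                yield (left, sub)

    trees = [(labels[1], labels[2])]
    for lab in labels[3:]:
        trees = [t2 for t in trees for t2 in insert(t, lab)]

    def to_newick(t):
        if isinstance(t, tuple):
            return "(" + ",".join(to_newick(x) for x in t) + ")"
        return t

    return [f"({labels[0]},{to_newick(t)});" for t in trees]


def brute_column_score(newick, column_of):
    """Minimum changes for one column by enumerating internal states."""
    tree = parse_newick(newick)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    states = sorted(set(column_of.values()))
    best = None
    for assign in itertools.product(states, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            state[id(leaf)] = column_of[leaf.label]
        cost = 0
        for node in tree.postorder():
            for child in node.children:
                cost += state[id(node)] != state[id(child)]
        if best is None or cost < best:
            best = cost
    return best


def brute_score(newick, matrix):
    total = 0
    for j in range(matrix.n_positions):
        col = {t: matrix.rows[i][j] for i, t in enumerate(matrix.taxa)}
        total += brute_column_score(newick, col)
    return total


# ---------------------------------------------------------------------------
# fitch_score


def test_invariant_column_zero_steps():
    m = CharacterMatrix(taxa=list("abcd"), rows=["A", "A", "A", "A"])
    assert P.fitch_score(parse_newick("((a,b),(c,d));"), m) == 0


def test_aabb_column_on_both_quartets():
    m = CharacterMatrix(taxa=["t1", "t2", "t3", "t4"], rows=["A", "A", "B", "B"])
    assert P.fitch_score(parse_newick("((t1,t2),(t3,t4));"), m) == 1
    assert P.fitch_score(parse_newick("((t1,t3),(t2,t4));"), m) == 2


def test_taxa_mismatch_rejected():
    m = CharacterMatrix(taxa=["a", "b", "c", "d"], rows=["A"] * 4)
    with pytest.raises(ValueError):
        P.fitch_score(parse_newick("((a,b),(c,x));"), m)


@pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
def test_fitch_matches_bruteforce_all_topologies(n_taxa, seed):
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    rows = ["".join(rng.choice(list("ACGT"), size=5)) for _ in labels]
    m = CharacterMatrix(taxa=labels, rows=rows)
    for nwk in all_topologies(labels):
        assert P.fitch_score(parse_newick(nwk), m) == brute_score(nwk, m)


def test_score_invariant_under_rerooting():
    rng = np.random.default_rng(9)
    labels = [f"t{i}" for i in range(8)]
    rows = ["".join(rng.choice(list("ACDEFG"), size=6)) for _ in labels]
    m = CharacterMatrix(taxa=labels, rows=rows)
    t = P.random_addition_tree(m, seed=4)
    base = P.fitch_score(t, m)
    for taxon in labels:
        rerooted = P.root_with_outgroup(t, taxon)
        assert P.fitch_score(rerooted, m) == base


# ---------------------------------------------------------------------------
# random addition


def test_random_addition_deterministic():
    rng = np.random.default_rng(0)
    labels = [f"t{i}" for i in range(7)]
    rows = ["".join(rng.choice(list("ACGT"), size=8)) for _ in labels]
    m = CharacterMatrix(taxa=labels, rows=rows)
    t1 = P.random_addition_tree(m, seed=5)
    t2 = P.random_addition_tree(m, seed=5)
    assert t1.newick() == t2.newick()


def test_random_addition_four_taxa_optimal():
    m = CharacterMatrix(taxa=["t1", "t2", "t3", "t4"],
                        rows=["A", "A", "B", "B"])
    for seed in range(5):
        t = P.random_addition_tree(m, seed=seed)
        assert P.fitch_score(t, m) == 1  # the unique optimum over 3 topologies


def test_random_addition_beats_input_order_caterpillar():
    rng = np.random.default_rng(17)
    labels = [f"t{i}" for i in range(8)]
    rows = ["".join(rng.choice(list("ACGT"), size=12)) for _ in labels]
    m = CharacterMatrix(taxa=labels, rows=rows)
    # caterpillar in input order
    nwk = "(t0,(t1,(t2,(t3,(t4,(t5,(t6,t7)))))));"
    caterpillar_score = P.fitch_score(parse_newick(nwk), m)
    t = P.random_addition_tree(m, seed=1)
    assert P.fitch_score(t, m) <= caterpillar_score


# ---------------------------------------------------------------------------
# CNI search


def _planted_matrix_6():
    # planted topology ((a,b),(c,d),(e,f)) with clean synapomorphies
    taxa = list("abcdef")
    # four synapomorphic columns per cherry, no conflicting characters
    rows = [
        "AAAATTTTGGGG",  # a
        "AAAATTTTGGGG",  # b
        "CCCCGGGGGGGG",  # c
        "CCCCGGGGGGGG",  # d
        "CCCCTTTTAAAA",  # e
        "CCCCTTTTAAAA",  # f
    ]
    return CharacterMatrix(taxa=taxa, rows=rows)


def test_cni_fixed_point_at_optimum():
    m = CharacterMatrix(taxa=["a", "b", "c", "d", "e"],
                        rows=["AAA", "AAB", "BBB", "BBA", "BBB"])
    best_score = min(brute_score(nwk, m) for nwk in all_topologies(m.taxa))
    start = min((nwk for nwk in all_topologies(m.taxa)),
                key=lambda nwk: brute_score(nwk, m))
    out = P.cni_search(parse_newick(start), m)
    assert P.fitch_score(out, m) == best_score


def test_cni_recovers_global_optimum_6_taxa():
    m = _planted_matrix_6()
    scores = {nwk: brute_score(nwk, m) for nwk in all_topologies(m.taxa)}
    assert len(scores) == 105
    global_min = min(scores.values())
    optimal = {frozenset(parse_newick(n).bipartitions())
               for n, s in scores.items() if s == global_min}
    for seed in range(5):
        start = P.random_addition_tree(m, seed=seed)
        out = P.cni_search(start, m)
        assert P.fitch_score(out, m) == global_min
        assert frozenset(out.bipartitions()) in optimal


def test_cni_never_worse_than_start():
    rng = np.random.default_rng(23)
    labels = [f"t{i}" for i in range(7)]
    for trial in range(20):
        rows = ["".join(rng.choice(list("ACGT"), size=10)) for _ in labels]
        m = CharacterMatrix(taxa=labels, rows=rows)
        start = P.random_addition_tree(m, seed=trial)
        s0 = P.fitch_score(start, m)
        out = P.cni_search(start, m)
        assert P.fitch_score(out, m) <= s0


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_single_rep():
    m = _planted_matrix_6()
    trees = P.bootstrap(m, n_reps=1, seed=0, n_starts=2)
    assert len(trees) == 1


def test_bootstrap_deterministic():
    m = _planted_matrix_6()
    t1 = P.bootstrap(m, n_reps=3, seed=9, n_starts=2)
    t2 = P.bootstrap(m, n_reps=3, seed=9, n_starts=2)
    assert [t.newick() for t in t1] == [t.newick() for t in t2]


def test_bootstrap_recovers_planted_clades():
    m = _planted_matrix_6()
    trees = P.bootstrap(m, n_reps=100, seed=3, n_starts=3)
    ab = canon(["a", "b"], m.taxa)
    ef = canon(["e", "f"], m.taxa)
    n_ab = sum(ab in t.bipartitions() for t in trees)
    n_ef = sum(ef in t.bipartitions() for t in trees)
    assert n_ab >= 95 and n_ef >= 95


def test_bootstrap_invariant_matrix_score_zero():
    m = CharacterMatrix(taxa=list("abcde"), rows=["A"] * 5)
    trees = P.bootstrap(m, n_reps=3, seed=0, n_starts=2)
    for t in trees:
        assert P.fitch_score(t, m) == 0


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_trees():
    t = parse_newick("((a,b),((c,d),e));")
    cons = P.majority_consensus([t.copy() for _ in range(4)])
    assert cons.bipartitions() == t.bipartitions()
    sup = cons.bipartitions(with_support=True)
    assert all(v == 100.0 for v in sup.values())


def test_consensus_two_thirds_support():
    t1 = parse_newick("((a,b),(c,(d,e)));")
    t2 = parse_newick("((a,b),(d,(c,e)));")
    t3 = parse_newick("((a,c),(b,(d,e)));")
    cons = P.majority_consensus([t1, t2, t3])
    sup = cons.bipartitions(with_support=True)
    ab = canon(["a", "b"], "abcde")
    de = canon(["d", "e"], "abcde")
    assert round(sup[ab]) == 67
    assert round(sup[de]) == 67


def test_consensus_threshold_collapses_minority():
    t1 = parse_newick("((a,b),(c,(d,e)));")
    t2 = parse_newick("((a,c),(b,(d,e)));")
    t3 = parse_newick("((a,d),(c,(b,e)));")
    cons = P.majority_consensus([t1, t2, t3])  # ab in 1/3 = 33% -> collapsed
    assert canon(["a", "b"], "abcde") not in cons.bipartitions()


def test_consensus_inconsistent_leafsets_rejected():
    t1 = parse_newick("((a,b),(c,d));")
    t2 = parse_newick("((a,b),(c,e));")
    with pytest.raises(ValueError):
        P.majority_consensus([t1, t2])


def test_consensus_supports_are_exact_counts():
    trees = P.bootstrap(_planted_matrix_6(), n_reps=20, seed=5, n_starts=2)
    cons = P.majority_consensus(trees)
    sup = cons.bipartitions(with_support=True)
    for bip, pct in sup.items():
        count = sum(bip in t.bipartitions() for t in trees)
        assert pct == pytest.approx(100.0 * count / len(trees))


# ---------------------------------------------------------------------------
# rooting


def test_rooting_preserves_bipartitions():
    t = parse_newick("((a,b),((c,d),(e,f)));")
    rooted = P.root_with_outgroup(t, "e")
    assert rooted.bipartitions() == t.bipartitions()


def test_outgroup_is_root_child():
    t = parse_newick("((a,b),((c,d),(e,f)));")
    rooted = P.root_with_outgroup(t, "c")
    root_children = rooted.root.children
    assert any(c.is_leaf and c.label == "c" for c in root_children)


def test_root_unroot_roundtrip():
    t = parse_newick("((a,b),((c,d),(e,f)));")
    r1 = P.root_with_outgroup(t, "a")
    r2 = P.root_with_outgroup(r1, "f")
    assert r2.bipartitions() == t.bipartitions()


def test_rooting_missing_taxon():
    t = parse_newick("((a,b),(c,d));")
    with pytest.raises(ValueError):
        P.root_with_outgroup(t, "zz")
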