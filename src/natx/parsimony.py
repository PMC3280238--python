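"""From-scratch maximum-parsimony inference.

Fitch small parsimony (unordered multistate characters, unit cost) with:

* random-addition starting trees (stepwise insertion at the best edge),
* close-neighbor-interchange hill climbing (level 1 = single NNI moves,
  level 2 = pairs of NNI moves explored from local optima),
* nonparametric bootstrap over matrix columns,
* majority-rule consensus with sub-threshold collapse,
* outgroup rooting.

Character states are encoded as bitmasks and all per-column work is
vectorized with numpy; identical columns are collapsed to weighted
patterns.  Scores of candidate rearrangements are computed exactly from
cached downpass/uppass state sets, so a full search never rescans the
whole tree per candidate.
"""

from __future__ import annotations

import numpy as np

from .align import CharacterMatrix
from .tree import Node, Tree

__all__ = [
    "fitch_score",
    "random_addition_tree",
    "cni_search",
    "bootstrap",
    "majority_consensus",
    "root_with_outgroup",
]


# ---------------------------------------------------------------------------
# encoding


class _Encoded:
    """Character matrix as bitmask patterns with column weights."""

    def __init__(self, matrix: CharacterMatrix, weights: np.ndarray | None = None):
        self.taxa = list(matrix.taxa)
        alphabet = sorted(set("".join(matrix.rows)))
        if len(alphabet) > 32:
            raise ValueError("more than 32 character states")
        bit = {c: np.uint32(1 << i) for i, c in enumerate(alphabet)}
        n, m = len(self.taxa), matrix.n_positions
        full = np.zeros((n, m), dtype=np.uint32)
        for i, row in enumerate(matrix.rows):
            for j, c in enumerate(row):
                full[i, j] = bit[c]
        if weights is None:
            weights = np.ones(m, dtype=np.int64)
        # collapse identical weighted columns
        cols, inverse = np.unique(full, axis=1, return_inverse=True)
        w = np.zeros(cols.shape[1], dtype=np.int64)
        np.add.at(w, inverse.ravel(), weights)
        keep = w > 0
        self.codes = np.ascontiguousarray(cols[:, keep])
        self.weights = w[keep]
        self.m = self.codes.shape[1]


def _merge(sa, ca, sb, cb):
    """Fitch set merge: intersection if non-empty else union with +1 step."""
    inter = sa & sb
    disjoint = inter == 0
    return np.where(disjoint, sa | sb, inter), ca + cb + disjoint


# ---------------------------------------------------------------------------
# standalone scoring on public trees


def fitch_score(tree: Tree, matrix: CharacterMatrix) -> int:
    """Minimum number of substitutions for ``matrix`` on ``tree``.

    The score is independent of root placement.  Multifurcating nodes are
    merged child-by-child (exact for binary trees, which is what the
    search produces).
    """
    enc = _Encoded(matrix)
    if sorted(tree.leaf_names()) != sorted(enc.taxa):
        raise ValueError("tree taxa do not match matrix taxa")
    index = {t: i for i, t in enumerate(enc.taxa)}
    total = np.zeros(enc.m, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = enc.codes[index[node.label]]
            continue
        s = sets.pop(id(node.children[0]))
        c = np.zeros(enc.m, dtype=np.int64)
        for child in node.children[1:]:
            s, c = _merge(s, c, sets.pop(id(child)), 0)
        sets[id(node)] = s
        total += c
    return int((total * enc.weights).sum())


# ---------------------------------------------------------------------------
# search engine


class _SN:
    __slots__ = ("children", "parent", "leaf", "idx")

    def __init__(self, leaf: int = -1):
        self.children: list["_SN"] = []
        self.parent: "_SN | None" = None
        self.leaf = leaf  # taxon index, -1 for internal
        self.idx = -1


class _Engine:
    """Unrooted binary tree handled as rooted at the edge of one leaf.

    ``self.handle`` is that leaf; its single child is the rest of the tree.
    Every other internal node has exactly two children.
    """

    def __init__(self, enc: _Encoded):
        self.enc = enc
        self.handle: _SN | None = None
        self._nodes: list[_SN] = []
        self.down_set = self.down_cost = self.rest_set = self.rest_cost = None
        self.total = 0

    # -- construction -------------------------------------------------------

    def start_triplet(self, t0: int, t1: int, t2: int) -> None:
        self.handle = _SN(t0)
        inner = _SN()
        inner.children = [_SN(t1), _SN(t2)]
        for c in inner.children:
            c.parent = inner
        self.handle.children = [inner]
        inner.parent = self.handle

    @classmethod
    def from_tree(cls, tree: Tree, enc: _Encoded) -> "_Engine":
        """Orient an arbitrary (possibly rooted) binary tree at leaf 0."""
        index = {t: i for i, t in enumerate(enc.taxa)}
        # undirected adjacency, suppressing a degree-2 root
        adj: dict[int, list] = {}
        objs: dict[int, object] = {}

        def link(a, b):
            adj.setdefault(id(a), []).append(b)
            adj.setdefault(id(b), []).append(a)
            objs[id(a)] = a
            objs[id(b)] = b

        for node in tree.postorder():
            for child in node.children:
                link(node, child)
        root = tree.root
        if len(root.children) == 2 and root.parent is None:
            a, b = root.children
            adj[id(a)].remove(root)
            adj[id(b)].remove(root)
            adj[id(a)].append(b)
            adj[id(b)].append(a)
            del adj[id(root)]

        start = tree.find(enc.taxa[0])
        eng = cls(enc)
        eng.handle = _SN(index[start.label])

        def build(obj, came_from) -> _SN:
            nbrs = [n for n in adj[id(obj)] if n is not came_from]
            if not nbrs:
                if not obj.is_leaf:
                    raise ValueError("tree is not binary")
                return _SN(index[obj.label])
            if len(nbrs) != 2:
                raise ValueError("tree is not a binary unrooted topology")
            node = _SN()
            node.children = [build(n, obj) for n in nbrs]
            for c in node.children:
                c.parent = node
            return node

        first = build(adj[id(start)][0], start)
        eng.handle.children = [first]
        first.parent = eng.handle
        return eng

    def to_tree(self) -> Tree:
        def conv(sn: _SN) -> Node:
            if sn.leaf >= 0:
                return Node(self.enc.taxa[sn.leaf])
            node = Node()
            for c in sn.children:
                node.add(conv(c))
            return node

        root = Node()
        root.add(Node(self.enc.taxa[self.handle.leaf]))
        root.add(conv(self.handle.children[0]))
        return Tree(root)

    # -- passes -------------------------------------------------------------

    def _postorder(self) -> list:
        out, stack = [], [self.handle.children[0]]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        out.reverse()
        return out

    def refresh(self) -> None:
        """Recompute down/rest passes and the total score."""
        enc = self.enc
        order = self._postorder()
        self._nodes = order
        N, m = len(order), enc.m
        for i, n in enumerate(order):
            n.idx = i
        down_set = np.empty((N, m), dtype=np.uint32)
        down_cost = np.zeros((N, m), dtype=np.int32)
        for n in order:
            if n.leaf >= 0:
                down_set[n.idx] = enc.codes[n.leaf]
            else:
                a, b = n.children
                down_set[n.idx], down_cost[n.idx] = _merge(
                    down_set[a.idx], down_cost[a.idx],
                    down_set[b.idx], down_cost[b.idx])
        handle_code = enc.codes[self.handle.leaf]
        rest_set = np.empty((N, m), dtype=np.uint32)
        rest_cost = np.zeros((N, m), dtype=np.int32)
        top = self.handle.children[0]
        rest_set[top.idx] = handle_code
        for n in reversed(order):
            if n.leaf >= 0:
                continue
            a, b = n.children
            rest_set[a.idx], rest_cost[a.idx] = _merge(
                rest_set[n.idx], rest_cost[n.idx],
                down_set[b.idx], down_cost[b.idx])
            rest_set[b.idx], rest_cost[b.idx] = _merge(
                rest_set[n.idx], rest_cost[n.idx],
                down_set[a.idx], down_cost[a.idx])
        self.down_set, self.down_cost = down_set, down_cost
        self.rest_set, self.rest_cost = rest_set, rest_cost
        _, cost = _merge(down_set[top.idx], down_cost[top.idx],
                         handle_code, np.zeros(m, dtype=np.int32))
        self.total = int((cost * enc.weights).sum())

    # -- stepwise addition --------------------------------------------------

    def insertion_deltas(self, taxon: int):
        """Extra steps from attaching ``taxon`` to the edge above each node."""
        x = self.enc.codes[taxon]
        edge_set, _ = _merge(self.down_set, self.down_cost,
                             self.rest_set, self.rest_cost)
        miss = ((edge_set & x) == 0).astype(np.int64)
        return miss @ self.enc.weights

    def insert_leaf(self, taxon: int, at: _SN) -> None:
        parent = at.parent
        joint = _SN()
        leaf = _SN(taxon)
        parent.children[parent.children.index(at)] = joint
        joint.parent = parent
        joint.children = [at, leaf]
        at.parent = joint
        leaf.parent = joint

    # -- NNI ----------------------------------------------------------------

    def _internal_edges(self) -> list:
        out = []
        for n in self._nodes:
            if n.leaf >= 0:
                continue
            p = n.parent
            if p is self.handle or p is None or p.leaf >= 0:
                continue
            out.append(n)
        return out

    def nni_scores(self):
        """Exact totals of the two alternative arrangements at each edge.

        Returns ``(edges, totals)`` with ``totals`` of shape (E, 2):
        column 0 swaps the second child with the sibling, column 1 swaps
        the first child.
        """
        edges = self._internal_edges()
        if not edges:
            return edges, np.zeros((0, 2), dtype=np.int64)
        iA = np.array([e.children[0].idx for e in edges])
        iB = np.array([e.children[1].idx for e in edges])
        iC = np.array([(e.parent.children[1] if e.parent.children[0] is e
                        else e.parent.children[0]).idx for e in edges])
        iV = np.array([e.parent.idx for e in edges])
        sA, cA = self.down_set[iA], self.down_cost[iA]
        sB, cB = self.down_set[iB], self.down_cost[iB]
        sC, cC = self.down_set[iC], self.down_cost[iC]
        sD, cD = self.rest_set[iV], self.rest_cost[iV]
        w = self.enc.weights

        def arrangement(s1, c1, s2, c2, s3, c3):
            su, cu = _merge(s1, c1, s2, c2)
            sv, cv = _merge(s3, c3, sD, cD)
            _, cost = _merge(su, cu, sv, cv)
            return cost @ w

        totals = np.stack([
            arrangement(sA, cA, sC, cC, sB, cB),  # B <-> C
            arrangement(sC, cC, sB, cB, sA, cA),  # A <-> C
        ], axis=1)
        return edges, totals

    @staticmethod
    def apply_nni(edge: _SN, which: int) -> None:
        """Swap a child of ``edge`` with its sibling; involution."""
        parent = edge.parent
        sib_pos = 1 if parent.children[0] is edge else 0
        sib = parent.children[sib_pos]
        child_pos = 1 if which == 0 else 0
        child = edge.children[child_pos]
        edge.children[child_pos] = sib
        parent.children[sib_pos] = child
        sib.parent = edge
        child.parent = parent


def _random_addition(enc: _Encoded, rng: np.random.Generator) -> _Engine:
    n = len(enc.taxa)
    order = list(rng.permutation(n))
    eng = _Engine(enc)
    if n == 1:
        eng.handle = _SN(order[0])
        return eng
    if n == 2:
        eng.handle = _SN(order[0])
        other = _SN(order[1])
        eng.handle.children = [other]
        other.parent = eng.handle
        return eng
    eng.start_triplet(order[0], order[1], order[2])
    for taxon in order[3:]:
        eng.refresh()
        deltas = eng.insertion_deltas(taxon)
        best = int(np.argmin(deltas))  # ties -> lowest postorder index
        eng.insert_leaf(taxon, eng._nodes[best])
    eng.refresh()
    return eng


def _hill_climb(eng: _Engine, level: int = 2) -> None:
    """Greedy CNI: steepest single NNI moves, then NNI pairs at optima."""
    eng.refresh()
    while True:
        edges, totals = eng.nni_scores()
        if len(edges) == 0:
            return
        flat = int(np.argmin(totals))
        e, which = flat // 2, flat % 2
        if totals[e, which] < eng.total:
            eng.apply_nni(edges[e], which)
            eng.refresh()
            continue
        if level < 2:
            return
        # second-order neighborhood from this local optimum
        improved = False
        base = eng.total
        for e in range(len(edges)):
            for which in (0, 1):
                eng.apply_nni(edges[e], which)
                eng.refresh()
                edges2, totals2 = eng.nni_scores()
                if len(edges2) and totals2.min() < base:
                    flat2 = int(np.argmin(totals2))
                    eng.apply_nni(edges2[flat2 // 2], flat2 % 2)
                    eng.refresh()
                    improved = True
                    break
                eng.apply_nni(edges[e], which)  # revert (involution)
            if improved:
                break
        if not improved:
            eng.refresh()
            return


# ---------------------------------------------------------------------------
# public search API


def random_addition_tree(matrix: CharacterMatrix, seed: int) -> Tree:
    """Stepwise-addition starting tree: taxa in seeded random order, each
    placed on the edge that adds the fewest steps."""
    enc = _Encoded(matrix)
    rng = np.random.default_rng(seed)
    return _random_addition(enc, rng).to_tree()


def cni_search(start_tree: Tree, matrix: CharacterMatrix, level: int = 2) -> Tree:
    """Close-neighbor-interchange hill climbing from ``start_tree``.

    ``level`` 1 explores single NNI moves; ``level`` >= 2 additionally
    explores pairs of NNI moves from each local optimum.  The returned
    tree never scores worse than the start.
    """
    enc = _Encoded(matrix)
    if len(enc.taxa) < 4:
        return start_tree.copy()
    eng = _Engine.from_tree(start_tree, enc)
    _hill_climb(eng, level=level)
    return eng.to_tree()


def _search_once(enc: _Encoded, rng: np.random.Generator,
                 n_starts: int, level: int) -> tuple[int, _Engine]:
    best: tuple[int, _Engine] | None = None
    for _ in range(n_starts):
        eng = _random_addition(enc, rng)
        if len(enc.taxa) >= 4:
            _hill_climb(eng, level=level)
        else:
            eng.refresh()
        if best is None or eng.total < best[0]:
            best = (eng.total, eng)
    return best


def parsimony_tree(matrix: CharacterMatrix, seed: int = 0, n_starts: int = 10,
                   level: int = 2) -> tuple[Tree, int]:
    """Best tree over ``n_starts`` random-addition + CNI searches."""
    enc = _Encoded(matrix)
    rng = np.random.default_rng(seed)
    score, eng = _search_once(enc, rng, n_starts, level)
    return eng.to_tree(), score


def bootstrap(matrix: CharacterMatrix, n_reps: int = 500, seed: int = 0,
              n_starts: int = 10, level: int = 2) -> list:
    """Column bootstrap: each replicate resamples matrix columns with
    replacement and reruns the full search; returns one tree per replicate."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    m = matrix.n_positions
    children = np.random.SeedSequence(seed).spawn(n_reps)
    trees = []
    for child in children:
        rng = np.random.default_rng(child)
        cols = rng.integers(0, m, size=m)
        weights = np.bincount(cols, minlength=m).astype(np.int64)
        enc = _Encoded(matrix, weights=weights)
        _, eng = _search_once(enc, rng, n_starts, level)
        trees.append(eng.to_tree())
    return trees


# ---------------------------------------------------------------------------
# consensus and rooting


def _nest_clades(names: set, anchor: str, clades: list) -> Tree:
    """Build a rooted tree (anchor attached at the root) from nested clades.

    ``clades`` holds ``(leafset, support)`` pairs, leafsets excluding the
    anchor.  Incompatible clades are skipped.
    """
    root = Node()
    root.add(Node(anchor))
    crown = Node()
    root.add(crown)
    leaf_nodes = {}
    for name in sorted(names - {anchor}):
        leaf_nodes[name] = crown.add(Node(name))
    leafset: dict[int, frozenset] = {id(crown): frozenset(names - {anchor})}
    for name, node in leaf_nodes.items():
        leafset[id(node)] = frozenset([name])

    for clade, support in sorted(clades, key=lambda cs: (-len(cs[0]), sorted(cs[0]))):
        host = crown
        descended = True
        while descended:
            descended = False
            for child in host.children:
                ls = leafset[id(child)]
                if clade < ls:
                    host = child
                    descended = True
                    break
        inside = [c for c in host.children if leafset[id(c)] <= clade]
        covered = frozenset().union(*(leafset[id(c)] for c in inside)) if inside else frozenset()
        if covered != clade:
            continue  # incompatible with already-placed clades
        if len(inside) == len(host.children) and host is not crown:
            host.support = support  # clade already exists
            continue
        new = Node()
        new.support = support
        for c in inside:
            host.children.remove(c)
            new.add(c)
        host.add(new)
        leafset[id(new)] = clade
    return Tree(root)


def majority_consensus(trees: list, collapse_below: float = 50.0) -> Tree:
    """Majority-rule consensus: keep bipartitions present in at least
    ``collapse_below`` percent of trees, annotated with that percentage."""
    if not trees:
        raise ValueError("no trees given")
    names = set(trees[0].leaf_names())
    counts: dict[frozenset, int] = {}
    for t in trees:
        if set(t.leaf_names()) != names:
            raise ValueError("trees have inconsistent leaf sets")
        for bip in t.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    n = len(trees)
    anchor = min(names)
    clades = []
    for bip, c in counts.items():
        pct = 100.0 * c / n
        if pct >= collapse_below:
            # canonical bipartitions exclude the smallest leaf == anchor
            clades.append((bip, pct))
    return _nest_clades(names, anchor, clades)


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Re-root so the outgroup leaf is a child of the root.

    The tree is rebuilt from its bipartition set, which re-rooting leaves
    unchanged; edge supports follow their bipartitions.
    """
    names = set(tree.leaf_names())
    if outgroup not in names:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    bips = tree.bipartitions(with_support=True)
    clades = []
    for bip, support in bips.items():
        side = bip if outgroup not in bip else frozenset(names - bip)
        clades.append((side, support))
    return _nest_clades(names, outgroup, clades)
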