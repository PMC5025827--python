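"""Heuristic maximum-parsimony tree inference and tree comparison.

The search is replicated random-addition-sequence stepwise addition
followed by steepest-descent SPR; equally parsimonious topologies found
across replicates are pooled and summarized by strict consensus.  Small
problems can be solved exactly with :func:`exhaustive_search`, which the
test suite uses as an oracle for the heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _fitch
from ._fitch import PatternData, encode_patterns
from .matrix_io import CharacterMatrix, RootedTree, reconcile_taxa

__all__ = [
    "TreeSearchResult",
    "tree_length",
    "heuristic_search",
    "exhaustive_search",
    "bootstrap_support",
    "support_from_tree_sets",
    "robinson_foulds",
    "strict_consensus",
    "unrooted_bipartitions",
    "root_with_outgroup",
]


# ---------------------------------------------------------------------------
# conversions between search topologies and RootedTree
# ---------------------------------------------------------------------------


def _topology_to_rooted(
    nbrs: dict[int, list[int]],
    taxa: list[str],
    root_edge: tuple[int, int] | None = None,
) -> RootedTree:
    if root_edge is None:
        leaf = min(u for u in nbrs if u < len(taxa))
        root_edge = (leaf, nbrs[leaf][0])
    u, v = root_edge
    tree = RootedTree()

    def build(node: int, come_from: int, parent_id: int) -> None:
        label = taxa[node] if node < len(taxa) else None
        nid = tree.add_child(parent_id, label=label)
        for nxt in nbrs[node]:
            if nxt != come_from:
                build(nxt, node, nid)

    build(u, v, tree.root)
    build(v, u, tree.root)
    return tree


def _rooted_to_topology(
    tree: RootedTree, taxa: list[str]
) -> dict[int, list[int]]:
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    ids: dict[int, int] = {}
    next_internal = n

    def tid(node: int) -> int:
        nonlocal next_internal
        if node not in ids:
            if tree.is_leaf(node):
                ids[node] = index[tree.labels[node]]
            else:
                ids[node] = next_internal
                next_internal += 1
        return ids[node]

    nbrs: dict[int, list[int]] = {}
    for parent, child in tree.edges():
        p, c = tid(parent), tid(child)
        nbrs.setdefault(p, []).append(c)
        nbrs.setdefault(c, []).append(p)
    r = tid(tree.root)
    if len(nbrs[r]) == 2:  # suppress a degree-2 root
        a, b = nbrs[r]
        nbrs[a][nbrs[a].index(r)] = b
        nbrs[b][nbrs[b].index(r)] = a
        del nbrs[r]
    return nbrs


# ---------------------------------------------------------------------------
# tree length (supports multifurcations and ambiguity via Hartigan counts)
# ---------------------------------------------------------------------------


def tree_length(matrix: CharacterMatrix, tree: RootedTree) -> int:
    """Sum over all columns of the per-character minimum change count."""
    matrix = reconcile_taxa(matrix, tree)
    patterns = encode_patterns(matrix)
    masks = patterns.masks
    row = {t: i for i, t in enumerate(patterns.taxa)}
    k_max = max((len(c.alphabet) for c in matrix.columns), default=1)
    n_pat = masks.shape[1]
    down: dict[int, np.ndarray] = {}
    total = np.zeros(n_pat, dtype=np.int64)
    one = np.uint64(1)
    for node in tree.postorder():
        kids = tree.children(node)
        if not kids:
            down[node] = masks[row[tree.labels[node]]]
            continue
        counts = np.zeros((k_max, n_pat), dtype=np.int32)
        for child in kids:
            for s in range(k_max):
                counts[s] += ((down[child] >> np.uint64(s)) & one).astype(np.int32)
        kbest = counts.max(axis=0)
        total += len(kids) - kbest
        mask = np.zeros(n_pat, dtype=np.uint64)
        for s in range(k_max):
            mask |= (counts[s] == kbest).astype(np.uint64) << np.uint64(s)
        down[node] = mask
    return int(np.dot(patterns.weights, total))


# ---------------------------------------------------------------------------
# heuristic and exhaustive search
# ---------------------------------------------------------------------------


@dataclass
class TreeSearchResult:
    """Pooled outcome of replicated parsimony searches."""

    best_length: int
    best_trees: list[RootedTree]
    consensus: RootedTree
    replicate_lengths: list[int]

    @property
    def n_best(self) -> int:
        return len(self.best_trees)


def _search_patterns(
    patterns: PatternData,
    n_replicates: int,
    seed_base: tuple[int, ...],
    weights: np.ndarray | None = None,
) -> tuple[float, list[dict[int, list[int]]], list[float]]:
    best_score = np.inf
    best: dict[frozenset, dict[int, list[int]]] = {}
    lengths = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed_base + (rep,)))
        topo = _fitch.random_addition_tree(patterns, rng, weights)
        topo, score = _fitch.spr_hill_climb(topo, patterns, weights)
        lengths.append(score)
        if score < best_score - 1e-9:
            best_score = score
            best = {}
        if abs(score - best_score) <= 1e-9:
            best[_fitch.topology_bipartitions(topo, patterns.n_taxa)] = topo
    return best_score, list(best.values()), lengths


def heuristic_search(
    matrix: CharacterMatrix, n_replicates: int = 10, seed: int | None = None
) -> TreeSearchResult:
    """Replicated random-addition + SPR search; deterministic under seed."""
    if matrix.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    patterns = encode_patterns(matrix)
    score, topos, lengths = _search_patterns(
        patterns, n_replicates, (0 if seed is None else seed,)
    )
    trees = [_topology_to_rooted(t, patterns.taxa) for t in topos]
    return TreeSearchResult(
        int(round(score)), trees, strict_consensus(trees),
        [int(round(x)) for x in lengths],
    )


def exhaustive_search(matrix: CharacterMatrix) -> tuple[int, list[RootedTree]]:
    """Exact optimum by enumerating all unrooted binary topologies (<=9 taxa)."""
    if matrix.n_taxa > 9:
        raise ValueError("exhaustive search limited to 9 taxa")
    patterns = encode_patterns(matrix)
    best = np.inf
    best_topos = []
    for topo in _fitch.all_topologies(patterns.n_taxa):
        s = _fitch.tree_score(topo, patterns)
        if s < best - 1e-9:
            best = s
            best_topos = [topo]
        elif abs(s - best) <= 1e-9:
            best_topos.append(topo)
    trees = [_topology_to_rooted(t, patterns.taxa) for t in best_topos]
    return int(round(best)), trees


# ---------------------------------------------------------------------------
# bootstrap support
# ---------------------------------------------------------------------------


def support_from_tree_sets(
    tree_sets: list[list[RootedTree]],
) -> dict[frozenset, float]:
    """Bipartition support percentages from per-replicate best-tree sets.

    Each of the k equally parsimonious trees of a replicate contributes
    1/k to every bipartition it contains.
    """
    tally: dict[frozenset, float] = {}
    for trees in tree_sets:
        k = len(trees)
        for tree in trees:
            for bip in unrooted_bipartitions(tree):
                tally[bip] = tally.get(bip, 0.0) + 1.0 / k
    return {b: 100.0 * v / len(tree_sets) for b, v in tally.items()}


def bootstrap_support(
    matrix: CharacterMatrix,
    n_boot: int = 100,
    seed: int | None = None,
    search_replicates: int = 2,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap: resample columns, re-search, tally splits."""
    patterns = encode_patterns(matrix)
    rng = np.random.default_rng(seed)
    tree_sets = []
    for b in range(n_boot):
        w = patterns.bootstrap_weights(rng)
        _, topos, _ = _search_patterns(
            patterns, search_replicates, (0 if seed is None else seed, 7919, b),
            weights=w,
        )
        tree_sets.append([_topology_to_rooted(t, patterns.taxa) for t in topos])
    support = support_from_tree_sets(tree_sets)
    if not support:
        warnings.warn("no internal bipartition received support", stacklevel=2)
    return support


# ---------------------------------------------------------------------------
# bipartitions, RF distance, consensus, rooting
# ---------------------------------------------------------------------------


def unrooted_bipartitions(tree: RootedTree) -> frozenset:
    """Non-trivial unrooted leaf bipartitions, each reported as the side
    not containing the alphabetically first taxon (as a frozenset of
    labels)."""
    labels = frozenset(tree.leaf_labels())
    ref = min(labels)
    n = len(labels)
    out = set()
    for node in tree.preorder():
        if node == tree.root or tree.is_leaf(node):
            continue
        side = tree.clade_leaf_labels(node)
        if ref in side:
            side = labels - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def robinson_foulds(tree_a: RootedTree, tree_b: RootedTree) -> float:
    """Normalized RF distance in [0, 2]: the symmetric difference of
    non-trivial bipartition sets over their mean size."""
    la, lb = set(tree_a.leaf_labels()), set(tree_b.leaf_labels())
    if la != lb:
        raise ValueError("trees have different leaf sets")
    pa = unrooted_bipartitions(tree_a)
    pb = unrooted_bipartitions(tree_b)
    if not pa and not pb:
        return 0.0
    return len(pa ^ pb) / ((len(pa) + len(pb)) / 2)


def _tree_from_clades(labels: list[str], clades: set[frozenset]) -> RootedTree:
    """Build a rooted tree whose internal nodes are exactly *clades* (a
    laminar family over *labels*, full set implicit)."""
    tree = RootedTree()
    ordered = sorted(clades, key=len, reverse=True)
    node_of: dict[frozenset, int] = {frozenset(labels): tree.root}

    def attach_parent(item: frozenset) -> int:
        best = frozenset(labels)
        for c in ordered:
            if item < c and len(c) < len(best):
                best = c
        return node_of[best]

    for clade in ordered:
        node_of[clade] = tree.add_child(attach_parent(clade))
    for lab in labels:
        tree.labels[tree.add_child(attach_parent(frozenset([lab])))] = lab
    return tree


def strict_consensus(trees: list[RootedTree]) -> RootedTree:
    """Tree containing exactly the bipartitions common to all input trees."""
    if not trees:
        raise ValueError("no trees to summarize")
    labels = sorted(trees[0].leaf_labels())
    common = unrooted_bipartitions(trees[0])
    for t in trees[1:]:
        if set(t.leaf_labels()) != set(labels):
            raise ValueError("trees have different leaf sets")
        common = common & unrooted_bipartitions(t)
    # interpret each split as the clade not containing the reference taxon
    return _tree_from_clades(labels, set(common))


def root_with_outgroup(tree: RootedTree, outgroup: list[str]) -> RootedTree:
    """Re-root on the edge separating *outgroup* from the rest.

    Falls back to the terminal edge of the first outgroup taxon when no
    edge induces that exact split.
    """
    taxa = sorted(tree.leaf_labels())
    og = frozenset(outgroup)
    if not og <= set(taxa):
        raise ValueError("outgroup taxa missing from tree")
    nbrs = _rooted_to_topology(tree, taxa)
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    og_ids = frozenset(index[t] for t in og)
    for u, v in _fitch.topology_edges(nbrs):
        side = _leafset_on_side(nbrs, u, v, n)
        if side == og_ids or side == frozenset(range(n)) - og_ids:
            return _topology_to_rooted(nbrs, taxa, root_edge=(u, v))
    leaf = index[sorted(og)[0]]
    return _topology_to_rooted(nbrs, taxa, root_edge=(leaf, nbrs[leaf][0]))


def _leafset_on_side(nbrs, u, v, n_taxa) -> frozenset:
    side = set()
    stack = [v]
    seen = {u, v}
    while stack:
        x = stack.pop()
        if x < n_taxa:
            side.add(x)
        for y in nbrs[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return frozenset(side)
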