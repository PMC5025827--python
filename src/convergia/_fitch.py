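"""Bitmask Fitch machinery for unrooted-tree parsimony search.

Characters are collapsed to unique site patterns; each entry is a bitmask
over the column's alphabet (full mask = missing).  Trees under search are
unrooted and binary: leaves are ids ``0 .. n_taxa-1`` (rows of the pattern
matrix), internal nodes have degree 3.  Scoring roots the tree at a leaf
and runs vectorized Fitch passes over all patterns at once; subtree
regrafts are scored exactly with directional (up/down) state sets and the
three-way Hartigan join at the insertion point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix_io import CharacterMatrix

MAX_STATES = 63


@dataclass
class PatternData:
    """Unique site patterns with multiplicities."""

    masks: np.ndarray  # (n_taxa, n_patterns) uint64
    weights: np.ndarray  # (n_patterns,) float64
    taxa: list[str]
    column_pattern: np.ndarray  # (n_columns,) pattern index per original column

    @property
    def n_taxa(self) -> int:
        return self.masks.shape[0]

    def with_weights(self, weights: np.ndarray) -> "PatternData":
        return PatternData(self.masks, np.asarray(weights, float), self.taxa,
                           self.column_pattern)

    def bootstrap_weights(self, rng: np.random.Generator) -> np.ndarray:
        """Pattern weights after resampling original columns with replacement."""
        n_cols = self.column_pattern.size
        draw = rng.integers(0, n_cols, size=n_cols)
        return np.bincount(
            self.column_pattern[draw], minlength=self.weights.size
        ).astype(float)


def encode_patterns(matrix: CharacterMatrix) -> PatternData:
    n_taxa = matrix.n_taxa
    cols = np.empty((n_taxa, matrix.n_columns), dtype=np.uint64)
    for j, col in enumerate(matrix.columns):
        if len(col.alphabet) > MAX_STATES:
            raise ValueError(f"column {col.id!r}: more than {MAX_STATES} states")
        bit = {s: np.uint64(1 << i) for i, s in enumerate(col.alphabet)}
        for i, taxon in enumerate(matrix.taxa):
            m = np.uint64(0)
            for s in col.entries[taxon]:
                m |= bit[s]
            cols[i, j] = m
    uniq, col_to_pat, counts = np.unique(
        cols.T, axis=0, return_inverse=True, return_counts=True
    )
    return PatternData(
        np.ascontiguousarray(uniq.T), counts.astype(float), list(matrix.taxa),
        col_to_pat.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# unrooted topology helpers (adjacency dicts)
# ---------------------------------------------------------------------------


def copy_topology(nbrs: dict[int, list[int]]) -> dict[int, list[int]]:
    return {k: list(v) for k, v in nbrs.items()}


def topology_edges(nbrs: dict[int, list[int]]) -> list[tuple[int, int]]:
    return [(u, v) for u in nbrs for v in nbrs[u] if u < v]


def _rooted_orders(
    nbrs: dict[int, list[int]], root: int
) -> tuple[list[int], dict[int, int]]:
    """Postorder node list and parent map for the tree rooted at *root*."""
    parent = {root: -1}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in nbrs[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    order.reverse()
    return order, parent


def _fitch2(m1, c1, m2, c2):
    inter = m1 & m2
    nz = inter != 0
    mask = np.where(nz, inter, m1 | m2)
    return mask, c1 + c2 + (~nz)


def _downpass(nbrs, parent, postorder, masks):
    """Directional down sets/costs for every node, toward the root."""
    n_pat = masks.shape[1]
    down: dict[int, np.ndarray] = {}
    dcost: dict[int, np.ndarray] = {}
    for u in postorder:
        kids = [v for v in nbrs[u] if v != parent[u]]
        if not kids:
            down[u] = masks[u]
            dcost[u] = np.zeros(n_pat, dtype=np.int64)
        else:
            m, c = down[kids[0]], dcost[kids[0]]
            for k in kids[1:]:
                m, c = _fitch2(m, c, down[k], dcost[k])
            down[u] = m
            dcost[u] = c
    return down, dcost


def tree_score(nbrs: dict[int, list[int]], patterns: PatternData,
               weights: np.ndarray | None = None) -> float:
    """Weighted parsimony length of an unrooted binary tree."""
    w = patterns.weights if weights is None else weights
    root = min(u for u in nbrs if u < patterns.n_taxa)
    postorder, parent = _rooted_orders(nbrs, root)
    down, dcost = _downpass(nbrs, parent, postorder, patterns.masks)
    (c0,) = [v for v in nbrs[root]]
    cost = dcost[c0] + ((patterns.masks[root] & down[c0]) == 0)
    return float(np.dot(w, cost))


def _edge_attach_scores(
    nbrs, patterns, weights, root_leaf, A, a_cost
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Exact new-tree lengths for attaching a component (state set *A*,
    per-pattern internal cost *a_cost*) into every edge of the tree.

    Returns the edges (parent, child) and a parallel score array.
    """
    masks = patterns.masks
    postorder, parent = _rooted_orders(nbrs, root_leaf)
    down, dcost = _downpass(nbrs, parent, postorder, masks)
    n_pat = masks.shape[1]
    up: dict[int, np.ndarray] = {}
    ucost: dict[int, np.ndarray] = {}
    for u in reversed(postorder):  # preorder
        if u == root_leaf:
            continue
        p = parent[u]
        if p == root_leaf:
            up[u] = masks[root_leaf]
            ucost[u] = np.zeros(n_pat, dtype=np.int64)
        else:
            sibs = [v for v in nbrs[p] if v != u and v != parent[p]]
            m, c = up[p], ucost[p]
            for s in sibs:
                m, c = _fitch2(m, c, down[s], dcost[s])
            up[u] = m
            ucost[u] = c
    edges = [u for u in postorder if u != root_leaf]
    D = np.stack([down[u] for u in edges])
    U = np.stack([up[u] for u in edges])
    base = np.stack([dcost[u] + ucost[u] for u in edges])
    pair = ((A & D) | (A & U) | (D & U)) != 0
    triple = (A & D & U) != 0
    delta = 2 - pair.astype(np.int64) - triple.astype(np.int64)
    scores = (base + delta + a_cost) @ weights
    return [(parent[u], u) for u in edges], scores


def insert_on_edge(nbrs, edge: tuple[int, int], node: int, new_internal: int) -> None:
    """Attach *node* into *edge* via a fresh degree-3 internal node."""
    p, c = edge
    nbrs[p][nbrs[p].index(c)] = new_internal
    nbrs[c][nbrs[c].index(p)] = new_internal
    nbrs[new_internal] = [p, c, node]
    nbrs.setdefault(node, [])
    nbrs[node].append(new_internal)


def random_addition_tree(
    patterns: PatternData, rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> dict[int, list[int]]:
    """Stepwise addition with a random taxon order, best edge each step."""
    w = patterns.weights if weights is None else weights
    n = patterns.n_taxa
    order = list(rng.permutation(n))
    a, b, c = order[:3]
    hub = n  # internal ids start at n_taxa
    nbrs: dict[int, list[int]] = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
    next_internal = n + 1
    zero = np.zeros(patterns.masks.shape[1], dtype=np.int64)
    for leaf in order[3:]:
        root_leaf = min(u for u in nbrs if u < n)
        edges, scores = _edge_attach_scores(
            nbrs, patterns, w, root_leaf, patterns.masks[leaf], zero
        )
        best = int(np.argmin(scores))
        insert_on_edge(nbrs, edges[best], leaf, next_internal)
        next_internal += 1
    return nbrs


def _prune(nbrs, u, v):
    """Detach the v-side subtree of edge (u, v).  Returns (rest adjacency,
    freed internal id, pruned-root state set info) or None if degenerate."""
    rest = copy_topology(nbrs)
    rest[u].remove(v)
    rest[v].remove(u)
    if len(rest[u]) != 2:
        return None  # u is a leaf; rest would be that single leaf
    # splice u (now degree 2) out of the rest tree
    a, b = rest[u]
    rest[a][rest[a].index(u)] = b
    rest[b][rest[b].index(u)] = a
    del rest[u]
    # drop the pruned component from rest
    keep = set()
    stack = [a]
    seen = {a}
    while stack:
        x = stack.pop()
        keep.add(x)
        for y in rest[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    rest = {k: rest[k] for k in keep}
    return rest, u


def _sub_component(nbrs, u, v):
    """Adjacency of the v-side component of edge (u, v), detached from u."""
    sub = {}
    stack = [v]
    seen = {u, v}
    while stack:
        x = stack.pop()
        sub[x] = [y for y in nbrs[x] if y != u] if x == v else list(nbrs[x])
        for y in sub[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return sub


def _reroot_candidates(sub, v, masks, max_leaves, n_taxa):
    """State sets of the pruned component for each re-attachment point.

    Yields (reroot_edge or None, A, a_cost).  ``None`` keeps the original
    attachment at *v*; other candidates re-root the component on one of its
    edges (the TBR extension), enumerated only when the component has at
    most *max_leaves* leaves.
    """
    postorder, parent = _rooted_orders(sub, v)
    down, dcost = _downpass(sub, parent, postorder, masks)
    yield None, down[v], dcost[v]
    n_leaves = sum(1 for x in sub if x < n_taxa)
    if n_leaves > max_leaves or len(sub) < 3:
        return
    n_pat = masks.shape[1]
    up: dict[int, np.ndarray] = {}
    ucost: dict[int, np.ndarray] = {}
    for x in reversed(postorder):  # preorder
        if x == v:
            continue
        p = parent[x]
        sibs = [y for y in sub[p] if y != x and y != parent[p]]
        if p == v:
            if not sibs:  # v of degree 1 inside the component
                continue
            m, c = down[sibs[0]], dcost[sibs[0]]
            sibs = sibs[1:]
        else:
            if p not in up:
                continue
            m, c = up[p], ucost[p]
        for s in sibs:
            m, c = _fitch2(m, c, down[s], dcost[s])
        up[x] = m
        ucost[x] = c
        if parent[x] == v:
            continue  # same unrooted edge as the original attachment
        inter = down[x] & m
        nz = inter != 0
        A = np.where(nz, inter, down[x] | m)
        a_cost = dcost[x] + c + (~nz)
        yield (parent[x], x), A, a_cost


def _apply_move(nbrs, u, v, reroot_edge, target_edge):
    """Detach the v-side of (u, v), optionally re-root it, and re-attach."""
    rest, freed = _prune(nbrs, u, v)
    sub = _sub_component(nbrs, u, v)
    merged = copy_topology(rest)
    if reroot_edge is None:
        merged.update(copy_topology(sub))
        attach = v
    else:
        # splice the degree-2 boundary node v out of the component ...
        sub = copy_topology(sub)
        a, b = sub[v]
        sub[a][sub[a].index(v)] = b
        sub[b][sub[b].index(v)] = a
        del sub[v]
        # ... and re-insert it on the chosen component edge
        x, y = reroot_edge
        if v in (x, y):  # original boundary edge; dissolve to the spliced edge
            x, y = a, b
        sub[x][sub[x].index(y)] = v
        sub[y][sub[y].index(x)] = v
        sub[v] = [x, y]
        merged.update(sub)
        attach = v
    insert_on_edge(merged, target_edge, attach, freed)
    return merged


def spr_hill_climb(
    nbrs: dict[int, list[int]],
    patterns: PatternData,
    weights: np.ndarray | None = None,
    max_rounds: int = 100,
    tbr_reroot_leaves: int = 4,
) -> tuple[dict[int, list[int]], float]:
    """Steepest-descent subtree pruning-regrafting to a local optimum.

    Pruned components with at most ``tbr_reroot_leaves`` leaves are also
    tried at every re-rooting (a bounded TBR extension that removes the
    worst small-tree local optima of plain SPR at modest cost).
    """
    w = patterns.weights if weights is None else weights
    masks = patterns.masks
    n = patterns.n_taxa
    current = tree_score(nbrs, patterns, w)
    n_pat = masks.shape[1]
    zero = np.zeros(n_pat, dtype=np.int64)
    for _ in range(max_rounds):
        best_score = current
        best_move = None
        for u, v in [(x, y) for x in nbrs for y in nbrs[x]]:
            pruned = _prune(nbrs, u, v)
            if pruned is None:
                continue
            rest, freed = pruned
            if len(rest) < 4:  # no alternative placement exists
                continue
            root_leaf = min(x for x in rest if x < n)
            if v < n and len(nbrs[v]) == 1:
                candidates = [(None, masks[v], zero)]
            else:
                sub = _sub_component(nbrs, u, v)
                candidates = list(
                    _reroot_candidates(sub, v, masks, tbr_reroot_leaves, n)
                )
            for reroot_edge, A, a_cost in candidates:
                edges, scores = _edge_attach_scores(
                    rest, patterns, w, root_leaf, A, a_cost
                )
                i = int(np.argmin(scores))
                if scores[i] < best_score - 1e-9:
                    best_score = float(scores[i])
                    best_move = (u, v, reroot_edge, edges[i])
        if best_move is None:
            break
        nbrs = _apply_move(nbrs, *best_move)
        current = best_score
    return nbrs, current


# ---------------------------------------------------------------------------
# bipartitions and topology identity
# ---------------------------------------------------------------------------


def topology_bipartitions(nbrs: dict[int, list[int]], n_taxa: int) -> frozenset:
    """Non-trivial leaf bipartitions, each as the side without leaf 0."""
    out = set()
    for u, v in topology_edges(nbrs):
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
        if 0 in side:
            side = set(range(n_taxa)) - side
        if 2 <= len(side) <= n_taxa - 2:
            out.add(frozenset(side))
    return frozenset(out)


def all_topologies(n_taxa: int):
    """Yield every unrooted binary topology on ``0..n_taxa-1`` (adjacency
    dicts), by sequential edge insertion."""

    def grow(nbrs, leaf, next_internal):
        if leaf == n_taxa:
            yield nbrs
            return
        for edge in topology_edges(nbrs):
            t = copy_topology(nbrs)
            insert_on_edge(t, edge, leaf, next_internal)
            yield from grow(t, leaf + 1, next_internal + 1)

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    hub = n_taxa
    base = {0: [hub], 1: [hub], 2: [hub], hub: [0, 1, 2]}
    yield from grow(base, 3, n_taxa + 1)
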