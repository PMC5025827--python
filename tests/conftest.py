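"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every full assignment of singleton states to internal
nodes and ambiguous leaves; they share no code with the package's dynamic
programming and exist to validate it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from convergia.matrix_io import CharacterColumn, CharacterMatrix, RootedTree


# ---------------------------------------------------------------------------
# brute-force parsimony oracle
# ---------------------------------------------------------------------------


def brute_force_mprs(column: CharacterColumn, tree: RootedTree):
    """All most-parsimonious full assignments, by exhaustive enumeration.

    Returns (min_changes, list of node->state dicts).
    """
    free: list[tuple[int, list[str]]] = []
    fixed: dict[int, str] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            states = column.entries[tree.labels[node]]
            if len(states) == 1:
                fixed[node] = next(iter(states))
            else:
                free.append((node, sorted(states)))
        else:
            free.append((node, list(column.alphabet)))
    edges = tree.edges()
    best = math.inf
    mprs: list[dict[int, str]] = []
    for combo in itertools.product(*(opts for _, opts in free)):
        assign = dict(fixed)
        assign.update({n: s for (n, _), s in zip(free, combo)})
        changes = sum(1 for p, c in edges if assign[p] != assign[c])
        if changes < best:
            best = changes
            mprs = [assign]
        elif changes == best:
            mprs.append(assign)
    return int(best), mprs


def random_rooted_tree(labels: list[str], rng: np.random.Generator) -> RootedTree:
    """Uniform-ish random rooted binary tree over the given leaf labels."""
    tree = RootedTree()

    def build_or_leaf(parent: int, labs: list[str]) -> None:
        if len(labs) == 1:
            tree.add_child(parent, label=labs[0])
        else:
            k = int(rng.integers(1, len(labs)))
            order = list(rng.permutation(labs))
            node = tree.add_child(parent)
            build_or_leaf(node, order[:k])
            build_or_leaf(node, order[k:])

    order = list(rng.permutation(labels))
    k = int(rng.integers(1, len(order)))
    build_or_leaf(tree.root, order[:k])
    build_or_leaf(tree.root, order[k:])
    return tree


def random_column(
    taxa: list[str],
    rng: np.random.Generator,
    max_states: int = 4,
    p_missing: float = 0.1,
    p_poly: float = 0.05,
    col_id: str = "c1",
) -> CharacterColumn:
    n_states = int(rng.integers(2, max_states + 1))
    alphabet = tuple(str(i) for i in range(n_states))
    entries = {}
    for t in taxa:
        u = rng.random()
        if u < p_missing:
            entries[t] = frozenset(alphabet)
        elif u < p_missing + p_poly and n_states > 2:
            entries[t] = frozenset(rng.choice(alphabet, size=2, replace=False))
        else:
            entries[t] = frozenset({str(rng.integers(n_states))})
    return CharacterColumn(col_id, alphabet, entries, "morphological")


def random_matrix(
    taxa: list[str], n_cols: int, rng: np.random.Generator, max_states: int = 3
) -> CharacterMatrix:
    cols = [
        random_column(taxa, rng, max_states=max_states, p_missing=0.05,
                      p_poly=0.0, col_id=f"c{j}")
        for j in range(n_cols)
    ]
    return CharacterMatrix(list(taxa), cols)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def quartet_tree() -> RootedTree:
    return RootedTree.from_newick("((Y1,Y2)n12,(Y3,Y4)n34);")


def make_column(tree_taxa, states, alphabet=None, col_id="c1", type_tag="morphological"):
    """Column from a per-taxon state string; '?' = missing, 'ab' = polymorphic."""
    observed = {ch for s in states for ch in s if ch != "?"}
    alpha = tuple(sorted(observed)) if alphabet is None else tuple(alphabet)
    entries = {}
    for t, s in zip(tree_taxa, states):
        entries[t] = frozenset(alpha) if s == "?" else frozenset(s)
    return CharacterColumn(col_id, alpha, entries, type_tag)


@pytest.fixture
def abab_column(quartet_tree) -> CharacterColumn:
    return make_column(["Y1", "Y2", "Y3", "Y4"], ["A", "B", "A", "B"])
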