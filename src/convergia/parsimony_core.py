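"""Unordered-character parsimony: minimum changes, MPR counting, homoplasy.

A most-parsimonious reconstruction (MPR) is a full assignment of singleton
states to every internal node *and* every ambiguous leaf that achieves the
minimum number of state changes on the tree.  All quantities here are
exact: MPRs are counted by dynamic programming with arbitrary-precision
integers, and fractions of MPRs consistent with a partial assignment are
obtained by clamping the queried nodes and re-running the counting DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .matrix_io import CharacterColumn, RootedTree

__all__ = [
    "MPRSummary",
    "HomoplasyIndices",
    "min_changes",
    "count_mprs",
    "assignment_fraction",
    "homoplasy_indices",
]

_INF = math.inf


class MPRSummary:
    """Per character-and-tree parsimony summary with exact MPR queries."""

    def __init__(self, column: CharacterColumn, tree: RootedTree):
        self.column = column
        self.tree = tree
        self.alphabet = tuple(column.alphabet)
        self._index = {s: i for i, s in enumerate(self.alphabet)}
        self._postorder = tree.postorder()
        # leaf constraint sets as index lists
        self._leaf_allowed: dict[int, list[int]] = {}
        for node in self._postorder:
            if tree.is_leaf(node):
                label = tree.labels.get(node)
                if label is None or label not in column.entries:
                    raise ValueError(f"leaf node {node} has no entry in column {column.id!r}")
                self._leaf_allowed[node] = sorted(
                    self._index[s] for s in column.entries[label]
                )
        self.min_changes, self.mpr_count = self._dp({})

    # -- DP ------------------------------------------------------------------

    def _dp(self, clamps: Mapping[int, int]) -> tuple[int, int]:
        """Min cost and exact count of optimal assignments, with optional
        per-node state clamps (node id -> alphabet index)."""
        k = len(self.alphabet)
        cost: dict[int, list[float]] = {}
        count: dict[int, list[int]] = {}
        for node in self._postorder:
            if node in self._leaf_allowed:
                allowed = self._leaf_allowed[node]
                c = [_INF] * k
                n = [0] * k
                for s in allowed:
                    c[s] = 0
                    n[s] = 1
            else:
                c = [0.0] * k
                n = [1] * k
                for child in self.tree.children(node):
                    cc, cn = cost[child], count[child]
                    best = min(cc)
                    # count of optimal child states, and of those != each s
                    total_best_n = sum(cn[t] for t in range(k) if cc[t] == best)
                    for s in range(k):
                        stay = cc[s]
                        move = best + 1
                        contrib = stay if stay <= move else move
                        if contrib == _INF:
                            c[s] = _INF
                            n[s] = 0
                            continue
                        ways = 0
                        if stay == contrib:
                            ways += cn[s]
                        if move == contrib:
                            ways += total_best_n - (cn[s] if cc[s] == best else 0)
                        c[s] += contrib
                        n[s] *= ways
            if node in clamps:
                s = clamps[node]
                c = [c[t] if t == s else _INF for t in range(k)]
                n = [n[t] if t == s else 0 for t in range(k)]
            cost[node] = c
            count[node] = n
        root_c = cost[self.tree.root]
        root_n = count[self.tree.root]
        best = min(root_c)
        if best == _INF:
            return -1, 0
        total = sum(root_n[s] for s in range(len(self.alphabet)) if root_c[s] == best)
        return int(best), total

    # -- queries -------------------------------------------------------------

    def assignment_fraction(self, assignment: Mapping[int, str]) -> Fraction:
        """Exact fraction of MPRs consistent with a node -> state assignment."""
        clamps: dict[int, int] = {}
        for node, state in assignment.items():
            if node not in self.tree._children:
                raise KeyError(f"unknown node {node}")
            if state not in self._index:
                raise ValueError(f"state {state!r} not in column alphabet")
            clamps[node] = self._index[state]
        if not clamps:
            return Fraction(1)
        cost, n = self._dp(clamps)
        if n == 0 or cost != self.min_changes:
            return Fraction(0)
        return Fraction(n, self.mpr_count)

    def admissible_states(self, node: int) -> list[str]:
        """States of *node* realized in at least one MPR."""
        if node in self._leaf_allowed and len(self._leaf_allowed[node]) == 1:
            return [self.alphabet[self._leaf_allowed[node][0]]]
        out = []
        for i, state in enumerate(self.alphabet):
            cost, n = self._dp({node: i})
            if n > 0 and cost == self.min_changes:
                out.append(state)
        return out


def min_changes(column: CharacterColumn, tree: RootedTree) -> int:
    """Minimum number of state changes over all internal-node and
    ambiguous-leaf assignments (missing leaves are free wildcards)."""
    return MPRSummary(column, tree).min_changes


def count_mprs(column: CharacterColumn, tree: RootedTree) -> int:
    """Number of distinct most-parsimonious full reconstructions."""
    return MPRSummary(column, tree).mpr_count


def assignment_fraction(
    summary: MPRSummary, assignment: Mapping[int, str]
) -> Fraction:
    return summary.assignment_fraction(assignment)


@dataclass(frozen=True)
class HomoplasyIndices:
    """ci/ri/rc homoplasy indices of a character on a tree.

    Min is the state count minus one (best possible tree), Max the changes
    required by a star-like worst tree, Obs the changes on the evaluated
    tree.  ``ci = Min/Obs``, ``ri = (Max-Obs)/(Max-Min)``, ``rc = ci*ri``;
    each is None when its denominator vanishes.
    """

    min_: int
    max_: int
    obs: int
    ci: float | None
    ri: float | None
    rc: float | None

    @property
    def defined(self) -> bool:
        return self.ci is not None and self.ri is not None


def homoplasy_indices(column: CharacterColumn, tree: RootedTree) -> HomoplasyIndices:
    obs = min_changes(column, tree)
    support = column.state_support()
    min_ = max(len(support) - 1, 0)
    n_unambiguous = sum(support.values())
    max_ = n_unambiguous - max(support.values(), default=0)
    ci = min_ / obs if obs > 0 else None
    ri = (max_ - obs) / (max_ - min_) if max_ != min_ else None
    rc = ci * ri if (ci is not None and ri is not None) else None
    return HomoplasyIndices(min_, max_, obs, ci, ri, rc)
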