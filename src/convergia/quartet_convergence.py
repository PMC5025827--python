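"""Quartet congruence between two rooted trees and per-quartet tallies.

A quartet is a set of four taxa (Y1, Y2 | Y3, Y4) such that, in *both*
input trees, Y1+Y2 and Y3+Y4 are each monophyletic to the exclusion of the
other pair and the root of the induced four-taxon tree lies on its internal
branch.  On a quartet a character's singleton states classify as
convergent -- (A,B,A,B) or (A,B,B,A) -- or consistent -- (A,A,B,B) -- with
A != B; anything else (missing, polymorphic, third states, autapomorphies)
is "other".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import MOLECULAR, MORPHOLOGICAL, CharacterColumn, CharacterMatrix, RootedTree

__all__ = [
    "Quartet",
    "QuartetTally",
    "find_congruent_quartets",
    "classify_quartet_character",
    "quartet_tally",
    "encode_singleton_states",
]

CONVERGENT = "convergent"
CONSISTENT = "consistent"
OTHER = "other"


@dataclass(frozen=True)
class Quartet:
    """Four taxa with (y1, y2) sister and (y3, y4) sister in both trees."""

    y1: str
    y2: str
    y3: str
    y4: str

    def taxa(self) -> tuple[str, str, str, str]:
        return (self.y1, self.y2, self.y3, self.y4)

    def canonical(self) -> "Quartet":
        a = tuple(sorted((self.y1, self.y2)))
        b = tuple(sorted((self.y3, self.y4)))
        a, b = sorted((a, b))
        return Quartet(a[0], a[1], b[0], b[1])


def _pair_clade_masks(tree: RootedTree, taxa: Sequence[str]) -> dict[tuple[int, int], int]:
    """Bitmask of leaves under the MRCA of each shared-taxon pair."""
    index = {t: i for i, t in enumerate(taxa)}
    leaf_node = {tree.labels[n]: n for n in tree.leaves()}
    # leaf mask below every node, restricted to the shared taxa
    mask: dict[int, int] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            lab = tree.labels[node]
            mask[node] = 1 << index[lab] if lab in index else 0
        else:
            m = 0
            for c in tree.children(node):
                m |= mask[c]
            mask[node] = m
    out = {}
    for i, j in itertools.combinations(range(len(taxa)), 2):
        m = tree.mrca([leaf_node[taxa[i]], leaf_node[taxa[j]]])
        out[(i, j)] = mask[m]
    return out


def _root_on_internal_branch(tree: RootedTree, q: Quartet) -> bool:
    """Condition (iii): restricted to the four taxa, the tree root projects
    onto the internal branch, i.e. neither cherry MRCA is ancestral to the
    other and to the root-side of the quartet."""
    nodes = {lab: tree.node_of(lab) for lab in q.taxa()}
    m12 = tree.mrca([nodes[q.y1], nodes[q.y2]])
    m34 = tree.mrca([nodes[q.y3], nodes[q.y4]])
    return m12 != m34 and not tree.is_ancestor(m12, m34) and not tree.is_ancestor(m34, m12)


def find_congruent_quartets(tree_a: RootedTree, tree_b: RootedTree) -> list[Quartet]:
    """All quartets satisfying the monophyly and rooting conditions in both
    trees, each reported once in canonical order."""
    shared = sorted(set(tree_a.leaf_labels()) & set(tree_b.leaf_labels()))
    if len(shared) < 4:
        warnings.warn("fewer than 4 shared taxa; no quartets", stacklevel=2)
        return []
    masks_a = _pair_clade_masks(tree_a, shared)
    masks_b = _pair_clade_masks(tree_b, shared)
    bit = {i: 1 << i for i in range(len(shared))}
    pairs = list(itertools.combinations(range(len(shared)), 2))
    quartets = []
    for (i, j), (k, l) in itertools.combinations(pairs, 2):
        if len({i, j, k, l}) != 4:
            continue
        other = bit[k] | bit[l]
        own = bit[i] | bit[j]
        if masks_a[(i, j)] & other or masks_b[(i, j)] & other:
            continue
        if masks_a[(k, l)] & own or masks_b[(k, l)] & own:
            continue
        q = Quartet(shared[i], shared[j], shared[k], shared[l]).canonical()
        if _root_on_internal_branch(tree_a, q) and _root_on_internal_branch(tree_b, q):
            quartets.append(q)
    return quartets


def classify_quartet_character(column: CharacterColumn, quartet: Quartet) -> str:
    states = []
    for taxon in quartet.taxa():
        entry = column.entries.get(taxon)
        if entry is None or len(entry) != 1:
            return OTHER
        states.append(next(iter(entry)))
    s1, s2, s3, s4 = states
    if s1 == s2 and s3 == s4 and s1 != s3:
        return CONSISTENT
    if s1 != s2 and s3 != s4 and {s3, s4} == {s1, s2}:
        return CONVERGENT
    return OTHER


def encode_singleton_states(
    matrix: CharacterMatrix,
) -> tuple[np.ndarray, dict[str, int], np.ndarray]:
    """Integer-code singleton entries (-1 for missing/polymorphic).

    Returns (codes[taxa, chars], taxon index, type tags per column).
    """
    taxon_index = {t: i for i, t in enumerate(matrix.taxa)}
    codes = np.full((matrix.n_taxa, matrix.n_columns), -1, dtype=np.int16)
    for j, col in enumerate(matrix.columns):
        state_idx = {s: i for i, s in enumerate(col.alphabet)}
        for t, states in col.entries.items():
            if len(states) == 1:
                codes[taxon_index[t], j] = state_idx[next(iter(states))]
    tags = np.array([c.type_tag for c in matrix.columns], dtype=object)
    return codes, taxon_index, tags


@dataclass
class QuartetTally:
    """Per-quartet and per-character convergence/consistency counts."""

    quartet_table: pd.DataFrame  # one row per quartet
    char_table: pd.DataFrame  # one row per character

    @property
    def analyzable(self) -> pd.DataFrame:
        """Quartets with molecular evidence (Cv_mol + Cs_mol > 0); the rest
        are excluded from morphological-vs-molecular comparisons."""
        t = self.quartet_table
        return t[t["analyzable"]]


def quartet_tally(matrix: CharacterMatrix, quartets: Sequence[Quartet]) -> QuartetTally:
    codes, taxon_index, tags = encode_singleton_states(matrix)
    is_morph = tags == MORPHOLOGICAL
    is_mol = tags == MOLECULAR
    n_chars = matrix.n_columns
    char_cv = np.zeros(n_chars, dtype=np.int64)
    char_cs = np.zeros(n_chars, dtype=np.int64)
    rows = []
    for q in quartets:
        try:
            idx = [taxon_index[t] for t in q.taxa()]
        except KeyError as exc:
            raise KeyError(f"quartet taxon {exc} absent from matrix") from exc
        s1, s2, s3, s4 = (codes[i] for i in idx)
        valid = (s1 >= 0) & (s2 >= 0) & (s3 >= 0) & (s4 >= 0)
        conv = valid & (s1 != s2) & (s3 != s4) & (
            ((s1 == s3) & (s2 == s4)) | ((s1 == s4) & (s2 == s3))
        )
        cons = valid & (s1 == s2) & (s3 == s4) & (s1 != s3)
        char_cv += conv
        char_cs += cons
        cv_morph = int(np.sum(conv & is_morph))
        cs_morph = int(np.sum(cons & is_morph))
        cv_mol = int(np.sum(conv & is_mol))
        cs_mol = int(np.sum(cons & is_mol))
        rows.append(
            {
                "y1": q.y1, "y2": q.y2, "y3": q.y3, "y4": q.y4,
                "cv_morph": cv_morph, "cs_morph": cs_morph,
                "cv_mol": cv_mol, "cs_mol": cs_mol,
                "n_morph": int(is_morph.sum()), "n_mol": int(is_mol.sum()),
                "analyzable": (cv_mol + cs_mol) > 0,
            }
        )
    quartet_table = pd.DataFrame(
        rows,
        columns=["y1", "y2", "y3", "y4", "cv_morph", "cs_morph", "cv_mol",
                 "cs_mol", "n_morph", "n_mol", "analyzable"],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(char_cs > 0, char_cv / np.maximum(char_cs, 1),
                         np.where(char_cv > 0, np.inf, np.nan))
    char_table = pd.DataFrame(
        {
            "id": matrix.column_ids(),
            "type": tags,
            "n_states": [c.observed_state_count for c in matrix.columns],
            "cv": char_cv,
            "cs": char_cs,
            "cv_cs": ratio,
        }
    )
    return QuartetTally(quartet_table, char_table)
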