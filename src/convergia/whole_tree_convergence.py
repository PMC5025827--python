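"""Branch-pair convergence/divergence tallies over a whole rooted tree.

For an independent branch pair (two edges sharing no node, neither
ancestral to the other) with edge states (X1 -> X3) and (X2 -> X4), a
character shows a convergence when X1 != X3, X2 != X4 and X3 == X4, and a
divergence when X1 != X3, X2 != X4 and X3 != X4.  Events are weighted by
the exact fraction of equally parsimonious reconstructions exhibiting them.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix_io import (
    MOLECULAR,
    MORPHOLOGICAL,
    CharacterMatrix,
    RootedTree,
    reconcile_taxa,
)
from .parsimony_core import MPRSummary
from .stats_tests import bh_qvalues, fisher_exact_2x2

__all__ = [
    "BranchPair",
    "PairEventCounts",
    "PairTestResult",
    "enumerate_independent_pairs",
    "pair_event_weights",
    "pair_fisher_tests",
    "state_binned_ratio",
    "analyze_whole_tree",
    "round_half_up",
]


@dataclass(frozen=True)
class BranchPair:
    """Two parent->child edges forming an independent pair."""

    parent1: int
    child1: int
    parent2: int
    child2: int

    def nodes(self) -> tuple[int, int, int, int]:
        return (self.parent1, self.child1, self.parent2, self.child2)

    def canonical(self) -> "BranchPair":
        e1, e2 = sorted([(self.parent1, self.child1), (self.parent2, self.child2)])
        return BranchPair(e1[0], e1[1], e2[0], e2[1])


def enumerate_independent_pairs(tree: RootedTree) -> list[BranchPair]:
    """Every unordered pair of edges sharing no node, with neither child on
    the root-to-other-child path."""
    edges = tree.edges()
    anc = {n: tree.ancestors(n) for n in tree.nodes()}
    pairs = []
    for (p1, c1), (p2, c2) in itertools.combinations(edges, 2):
        if len({p1, c1, p2, c2}) != 4:
            continue
        if c1 in anc[c2] or c2 in anc[c1]:
            continue
        pairs.append(BranchPair(p1, c1, p2, c2))
    return pairs


def pair_event_weights(
    summary: MPRSummary, pair: BranchPair
) -> tuple[Fraction, Fraction]:
    """Weighted (convergence, divergence) contribution of one character to
    one branch pair: sums of MPR fractions over joint edge-state
    assignments satisfying each condition."""
    nodes = pair.nodes()
    adm = [summary.admissible_states(n) for n in nodes]
    cv = Fraction(0)
    dv = Fraction(0)
    for x1, x3, x2, x4 in itertools.product(adm[0], adm[1], adm[2], adm[3]):
        if x1 == x3 or x2 == x4:
            continue
        frac = summary.assignment_fraction(
            {nodes[0]: x1, nodes[1]: x3, nodes[2]: x2, nodes[3]: x4}
        )
        if frac == 0:
            continue
        if x3 == x4:
            cv += frac
        else:
            dv += frac
    return cv, dv


@dataclass
class PairEventCounts:
    """Weighted event sums for one branch pair, split by character type."""

    cv: dict[str, float] = field(default_factory=dict)
    dv: dict[str, float] = field(default_factory=dict)
    n_chars: dict[str, int] = field(default_factory=dict)

    def add(self, type_tag: str, cv_w: float, dv_w: float) -> None:
        self.cv[type_tag] = self.cv.get(type_tag, 0.0) + float(cv_w)
        self.dv[type_tag] = self.dv.get(type_tag, 0.0) + float(dv_w)
        self.n_chars[type_tag] = self.n_chars.get(type_tag, 0) + 1


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves going up (24.67 -> 25)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PairTestResult:
    p_conv: float | None
    p_cvdv: float | None
    defined: bool


def pair_fisher_tests(counts: PairEventCounts) -> PairTestResult:
    """Fisher tests comparing convergence frequency and Cv/Dv between
    morphological and molecular characters for one branch pair.

    Weighted sums are rounded half-up to integers before testing.  Pairs
    with zero molecular convergence and divergence are undefined and must
    be excluded from summaries.
    """
    cv_m = round_half_up(counts.cv.get(MORPHOLOGICAL, 0.0))
    cv_o = round_half_up(counts.cv.get(MOLECULAR, 0.0))
    dv_m = round_half_up(counts.dv.get(MORPHOLOGICAL, 0.0))
    dv_o = round_half_up(counts.dv.get(MOLECULAR, 0.0))
    n_m = counts.n_chars.get(MORPHOLOGICAL, 0)
    n_o = counts.n_chars.get(MOLECULAR, 0)
    if cv_o == 0 and dv_o == 0:
        return PairTestResult(None, None, False)
    p_conv = fisher_exact_2x2(cv_m, n_m - cv_m, cv_o, n_o - cv_o)
    p_cvdv = fisher_exact_2x2(cv_m, dv_m, cv_o, dv_o)
    return PairTestResult(p_conv, p_cvdv, True)


def state_binned_ratio(
    per_char_ratios: Sequence[float],
    state_counts: Sequence[int],
    char_types: Sequence[str],
    bins: Sequence[Sequence[int]] | None = None,
) -> float:
    """State-count-matched morphological/molecular ratio of mean Cv/Dv.

    Characters are binned by observed state count (one bin per distinct
    count unless ``bins`` gives explicit groupings).  Per bin the ratio of
    mean morphological to mean molecular per-character Cv/Dv is computed;
    the result is the average over bins weighted by the number of
    morphological characters per bin.  Characters with undefined ratios
    (NaN, e.g. zero divergence) are excluded from bin means; bins lacking
    either character type are skipped with a warning.
    """
    ratios = np.asarray(per_char_ratios, dtype=float)
    states = np.asarray(state_counts, dtype=int)
    types = np.asarray(char_types, dtype=object)
    if not (ratios.size == states.size == types.size):
        raise ValueError("inputs must have equal lengths")
    if bins is None:
        bins = [[s] for s in sorted(set(states.tolist()))]
    num = 0.0
    denom = 0.0
    skipped = []
    for group in bins:
        in_bin = np.isin(states, list(group))
        morph = ratios[in_bin & (types == MORPHOLOGICAL)]
        mol = ratios[in_bin & (types == MOLECULAR)]
        weight = morph.size  # all morphological characters in the bin
        morph = morph[np.isfinite(morph)]
        mol = mol[np.isfinite(mol)]
        if morph.size == 0 or mol.size == 0 or np.mean(mol) == 0:
            skipped.append(tuple(group))
            continue
        num += weight * (np.mean(morph) / np.mean(mol))
        denom += weight
    if skipped:
        warnings.warn(f"bins skipped (one character type absent): {skipped}",
                      stacklevel=2)
    if denom == 0:
        raise ValueError("no bin contains both character types")
    return num / denom


def analyze_whole_tree(
    matrix: CharacterMatrix,
    tree: RootedTree,
    pairs: Iterable[BranchPair] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full branch-pair tally of weighted convergence/divergence events.

    Returns ``(pair_table, char_table)``.  The pair table has one row per
    independent branch pair with weighted Cv/Dv sums per character type,
    Fisher p-values and BH q-values (undefined pairs flagged).  The
    character table has per-character Cv/Dv sums over all pairs, the
    observed state count and the character type.
    """
    matrix = reconcile_taxa(matrix, tree)
    if pairs is None:
        pairs = enumerate_independent_pairs(tree)
    pairs = [p.canonical() for p in pairs]
    summaries = [MPRSummary(col, tree) for col in matrix.columns]

    pair_counts = [PairEventCounts() for _ in pairs]
    char_cv = np.zeros(len(summaries))
    char_dv = np.zeros(len(summaries))
    for j, summary in enumerate(summaries):
        tag = summary.column.type_tag
        for i, pair in enumerate(pairs):
            cv, dv = pair_event_weights(summary, pair)
            pair_counts[i].add(tag, float(cv), float(dv))
            char_cv[j] += float(cv)
            char_dv[j] += float(dv)

    rows = []
    for pair, counts in zip(pairs, pair_counts):
        test = pair_fisher_tests(counts)
        rows.append(
            {
                "pair": f"{pair.parent1}->{pair.child1}|{pair.parent2}->{pair.child2}",
                "cv_morph": counts.cv.get(MORPHOLOGICAL, 0.0),
                "dv_morph": counts.dv.get(MORPHOLOGICAL, 0.0),
                "cv_mol": counts.cv.get(MOLECULAR, 0.0),
                "dv_mol": counts.dv.get(MOLECULAR, 0.0),
                "n_morph": counts.n_chars.get(MORPHOLOGICAL, 0),
                "n_mol": counts.n_chars.get(MOLECULAR, 0),
                "defined": test.defined,
                "p_conv": test.p_conv,
                "p_cvdv": test.p_cvdv,
            }
        )
    pair_table = pd.DataFrame(rows)
    for col in ("p_conv", "p_cvdv"):
        mask = pair_table[col].notna()
        q = pd.Series(np.nan, index=pair_table.index)
        if mask.any():
            q.loc[mask] = bh_qvalues(pair_table.loc[mask, col].tolist())
        pair_table[col.replace("p_", "q_")] = q

    with np.errstate(divide="ignore", invalid="ignore"):
        char_ratio = np.where(char_dv > 0, char_cv / np.maximum(char_dv, 1e-300),
                              np.where(char_cv > 0, np.inf, np.nan))
    char_table = pd.DataFrame(
        {
            "id": [s.column.id for s in summaries],
            "type": [s.column.type_tag for s in summaries],
            "n_states": [s.column.observed_state_count for s in summaries],
            "cv": char_cv,
            "dv": char_dv,
            "cv_dv": char_ratio,
        }
    )
    return pair_table, char_table
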