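"""Statistical procedures used across the convergence analyses."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .matrix_io import MOLECULAR, MORPHOLOGICAL, CharacterMatrix

__all__ = [
    "BootstrapResult",
    "fisher_exact_2x2",
    "bh_qvalues",
    "bootstrap_majority_test",
    "resample_characters",
    "mann_whitney",
    "partial_correlation",
]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p-value for a 2x2 table, probability-mass rule.

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed that of the
    observed table.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in contingency table {cells}")
    if any(int(x) != x for x in cells):
        raise ValueError(f"non-integer cell in contingency table {cells}")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


@dataclass(frozen=True)
class BootstrapResult:
    n_replicates: int
    criterion: str
    p_value: float
    n_success: int


def resample_characters(
    matrix: CharacterMatrix, rng: np.random.Generator
) -> CharacterMatrix:
    """Bootstrap-resample columns with replacement, within each type tag."""
    cols = []
    for tag in (MORPHOLOGICAL, MOLECULAR):
        pool = matrix.columns_of_type(tag)
        if pool:
            idx = rng.integers(0, len(pool), size=len(pool))
            cols.extend(pool[i] for i in idx)
    other = [c for c in matrix.columns if c.type_tag not in (MORPHOLOGICAL, MOLECULAR)]
    cols.extend(other)
    return CharacterMatrix(list(matrix.taxa), cols)


def bootstrap_majority_test(
    matrix: CharacterMatrix,
    analysis: Callable[[CharacterMatrix], Sequence[tuple[float, float]]],
    B: int = 10_000,
    seed: int | None = None,
    criterion: str = ">50% of units show lower morphological than molecular convergence",
) -> BootstrapResult:
    """Character-bootstrap test of the morphological-vs-molecular contrast.

    ``analysis`` maps a resampled matrix to per-unit (morphological value,
    molecular value) pairs.  The returned P is the fraction of replicates in
    which more than half of the units favor the null, i.e. show a lower
    morphological than molecular value.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n_success = 0
    for _ in range(B):
        sample = resample_characters(matrix, rng)
        pairs = list(analysis(sample))
        if not pairs:
            continue
        lower = sum(1 for m, o in pairs if m < o)
        if lower > len(pairs) / 2:
            n_success += 1
    return BootstrapResult(B, criterion, n_success / B, n_success)


def mann_whitney(x: Sequence[float], y: Sequence[float], paired: bool = False) -> float:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    The paired branch tests within-pair differences by signed ranks, the
    usual nonparametric analogue when observations come in matched pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal lengths")
        if np.all(x == y):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return 1.0
        return float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> float:
    """First-order Pearson partial correlation r_xy.z.

    Returns NaN (with a warning) when any variable has zero variance or a
    controlling correlation is +-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal lengths")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if min(np.std(x), np.std(y), np.std(z)) == 0:
        warnings.warn("zero variance; partial correlation undefined", stacklevel=2)
        return float("nan")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        warnings.warn("controlling variable collinear; partial correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float((rxy - rxz * ryz) / denom)
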