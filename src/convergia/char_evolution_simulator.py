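"""Multistate character-evolution simulator on a fixed rooted tree.

Characters evolve by a discrete Markov chain under an N-state
equal-exchange model: the single-step transition matrix has every
off-diagonal entry equal to 0.01/N (a "1 PAM"-style step, uniform
equilibrium).  A branch of length t (expected substitutions per character
at relative rate 1) receives ``k ~ Poisson(100 * r * t)`` steps for a
character of relative rate r (deterministic ``round(100 * r * t)`` is
available as an alternative).  Per-character rates are drawn to achieve a
target Pearson correlation with the number of states and are normalized to
mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .matrix_io import (
    MOLECULAR,
    MORPHOLOGICAL,
    CharacterColumn,
    CharacterMatrix,
    RootedTree,
)

__all__ = [
    "DEFAULT_TREE_NEWICK",
    "StateCountDistribution",
    "default_morphological_states",
    "default_molecular_states",
    "SimConfig",
    "SimCharacter",
    "build_transition_matrix",
    "draw_rates",
    "simulate_character",
    "simulate_dataset",
    "iter_replicates",
]

# 46-taxon reference tree (topology and branch lengths of the mammalian
# nucleotide ML tree) used as the default simulation scaffold.
DEFAULT_TREE_NEWICK = (
    "((((((((1:0.0759,(2:0.0568,3:0.0467)47:0.0234)48:0.00318,(((4:0.0448,"
    "5:0.0626)49:0.00468,((6:0.0656,7:0.0707)50:0.00570,(8:0.0634,9:0.0616)"
    "51:0.00210)52:0.0142)53:0.0150,((10:0.0602,(((11:0.0383,(12:0.0233,"
    "13:0.0128)54:0.0165)55:0.00491,14:0.0721)56:0.00919,15:0.0666)57:0.00518)"
    "58:0.0222,16:0.0559)59:0.00143)60:0.000543)61:0.00249,(17:0.1007,"
    "(18:0.0849,(19:0.1390,20:0.1468)62:0.0152)63:0.00163)64:0.00940)65:0.0110,"
    "(((21:0.0989,22:0.0676)66:0.0303,(23:0.1102,((24:0.0777,25:0.1875)"
    "67:0.00944,(26:0.0941,27:0.1660)68:0.00225)69:0.0131)70:0.00528)71:0.00149,"
    "((28:0.0618,(29:0.0913,(30:0.0414,31:0.0231)72:0.0368)73:0.00438)74:0.00775,"
    "(32:0.00806,33:0.00966)75:0.0581)76:0.00177)77:0.00997)78:0.0107,"
    "(34:0.0664,35:0.0869)79:0.0309)80:0.00230,((36:0.0429,(37:0.1000,"
    "38:0.0439)81:0.00304)82:0.0133,(39:0.0695,((40:0.1506,41:0.0760)83:0.00679,"
    "42:0.1275)84:0.00331)85:0.00283)86:0.0300)87:0.1278,(43:0.0834,44:0.0739)"
    "88:0.1754)89:0.1518,(45:0.0454,46:0.0378)90:0.1518)91:0.0000;"
)


@dataclass(frozen=True)
class StateCountDistribution:
    """Probability distribution over per-character state counts N >= 2."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.probs):
            raise ValueError("values and probs must have equal lengths")
        if any(v < 2 for v in self.values):
            raise ValueError("state counts must be >= 2")
        if any(p < 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must be non-negative and sum to 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))

    @property
    def std(self) -> float:
        v = np.asarray(self.values, dtype=float)
        return float(np.sqrt(np.dot(self.probs, (v - self.mean) ** 2)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.asarray(self.values), size=size, p=np.asarray(self.probs))


def default_morphological_states() -> StateCountDistribution:
    """Mostly-binary profile: 75.2% binary with a geometric tail over 3-6.

    An approximation to the empirical morphological state-count spectrum
    (median 2); the exact histogram is configurable by the caller.
    """
    tail = 1.0 - 0.752
    w = np.array([8, 4, 2, 1], dtype=float)
    w = tail * w / w.sum()
    return StateCountDistribution((2, 3, 4, 5, 6), (0.752, *(float(x) for x in w)))


def default_molecular_states() -> StateCountDistribution:
    """Amino-acid-like profile over 2-20 states with median 5, 12.4% binary."""
    values = tuple(range(2, 21))
    probs = np.array(
        [0.124, 0.160, 0.180, 0.160, 0.120, 0.090, 0.060, 0.040, 0.025,
         0.014, 0.008, 0.006, 0.004, 0.003, 0.002, 0.002, 0.001, 0.0006,
         0.0004]
    )
    probs = probs / probs.sum()
    return StateCountDistribution(values, tuple(float(p) for p in probs))


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters; defaults mirror the reference experiment
    (50 replicates of 20,000 morphological + 40,000 molecular characters,
    rate-state correlation 0.64)."""

    tree: RootedTree = field(default_factory=lambda: RootedTree.from_newick(DEFAULT_TREE_NEWICK))
    n_morph: int = 20_000
    n_mol: int = 40_000
    n_replicates: int = 50
    morph_states: StateCountDistribution = field(default_factory=default_morphological_states)
    mol_states: StateCountDistribution = field(default_factory=default_molecular_states)
    rate_correlation: float = 0.64
    seed: int = 0
    steps_mode: str = "poisson"

    def __post_init__(self) -> None:
        if not -1 < self.rate_correlation < 1:
            raise ValueError("rate_correlation must lie in (-1, 1)")
        if min(self.n_morph, self.n_mol, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.steps_mode not in ("poisson", "round"):
            raise ValueError("steps_mode must be 'poisson' or 'round'")


@dataclass(frozen=True)
class SimCharacter:
    """One simulated character: leaf states plus generation metadata."""

    leaf_states: dict[str, int]
    n_states: int
    rate: float
    steps: int


def build_transition_matrix(N: int) -> np.ndarray:
    """N x N single-step matrix: off-diagonal 0.01/N, rows summing to 1."""
    if N < 2:
        raise ValueError("N must be >= 2")
    off = 0.01 / N
    M = np.full((N, N), off)
    np.fill_diagonal(M, 1.0 - off * (N - 1))
    return M


_RATE_FLOOR = 1e-3


def draw_rates(
    n_states: Sequence[int],
    rho: float,
    rng: np.random.Generator,
    distribution: StateCountDistribution | None = None,
) -> np.ndarray:
    """Positive relative rates with mean exactly 1 and corr(rate, N) ~ rho.

    For character i with state count n_i, an independent n'_i is drawn from
    the same state-count distribution and the raw rate is
    ``rho * z(n_i) + sqrt(1 - rho^2) * z(n'_i)`` with z() standardizing by
    the distribution's mean and SD.  The raw values are shifted positive
    (minimum mapped to a small floor) and rescaled to unit sample mean;
    both transformations preserve the correlation.
    """
    n = np.asarray(n_states, dtype=float)
    if n.size == 0:
        raise ValueError("n_states must be non-empty")
    if distribution is not None:
        mu, sd = distribution.mean, distribution.std
        n_prime = distribution.sample(rng, n.size).astype(float)
    else:
        mu, sd = float(np.mean(n)), float(np.std(n))
        n_prime = rng.choice(n, size=n.size)
    if sd == 0:
        import warnings

        warnings.warn("degenerate state-count distribution; rates all 1",
                      stacklevel=2)
        return np.ones(n.size)
    raw = rho * (n - mu) / sd + np.sqrt(1 - rho**2) * (n_prime - mu) / sd
    shifted = raw - raw.min() + _RATE_FLOOR
    return shifted / shifted.mean()


def _branch_steps(tree: RootedTree) -> list[tuple[int, int, float]]:
    out = []
    for parent, child in tree.edges():
        t = tree.length(child)
        if t is None:
            raise ValueError(f"branch to node {child} lacks a length")
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        out.append((parent, child, t))
    return out


def simulate_character(
    tree: RootedTree, N: int, r: float, rng: np.random.Generator,
    steps_mode: str = "poisson",
) -> SimCharacter:
    """Evolve one character from a uniform root state down the tree.

    A branch of length t receives ``k`` single-step transitions of the
    1-PAM matrix: ``k ~ Poisson(100*r*t)`` in the default (continuous-time
    style) mode, or the deterministic ``k = round(100*r*t)`` in ``round``
    mode.  Both give the same expected number of steps; the deterministic
    variant freezes branches shorter than ``0.005/r`` entirely.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if r <= 0:
        raise ValueError("rate must be positive")
    p_change = 0.01 * (N - 1) / N
    states = {tree.root: int(rng.integers(N))}
    steps = 0
    for parent, child, t in _branch_steps(tree):
        if steps_mode == "poisson":
            k = int(rng.poisson(100.0 * r * t))
        else:
            k = int(round(100.0 * r * t))
        m = int(rng.binomial(k, p_change)) if k > 0 else 0
        s = states[parent]
        for _ in range(m):
            s = (s + 1 + int(rng.integers(N - 1))) % N
        states[child] = s
        steps += m
    leaf_states = {tree.labels[n]: states[n] for n in tree.leaves()}
    return SimCharacter(leaf_states, N, r, steps)


def _simulate_block(
    tree: RootedTree,
    dist: StateCountDistribution,
    n_chars: int,
    rho: float,
    rng: np.random.Generator,
    type_tag: str,
    id_prefix: str,
    steps_mode: str,
) -> tuple[list[CharacterColumn], pd.DataFrame]:
    """Vectorized simulation of one character block (all characters at once,
    branch by branch)."""
    N = dist.sample(rng, n_chars).astype(np.int64)
    r = draw_rates(N, rho, rng, dist)
    p_change = 0.01 * (N - 1) / N
    leaf_order = [tree.labels[n] for n in tree.leaves()]
    state: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, N, size=n_chars).astype(np.int64)
    }
    steps = np.zeros(n_chars, dtype=np.int64)
    branches = _branch_steps(tree)
    for parent, child, t in branches:
        if steps_mode == "poisson":
            k = rng.poisson(100.0 * r * t)
        else:
            k = np.rint(100.0 * r * t).astype(np.int64)
        m = rng.binomial(k, p_change)
        s = state[parent].copy()
        jumps = int(m.max()) if m.size else 0
        for j in range(jumps):
            active = m > j
            if not np.any(active):
                break
            na = N[active]
            s[active] = (s[active] + 1 + rng.integers(0, na - 1)) % na
        state[child] = s
        steps += m
    leaf_codes = {tree.labels[n]: state[n] for n in tree.leaves()}

    columns = []
    for j in range(n_chars):
        observed = sorted({int(leaf_codes[t][j]) for t in leaf_order})
        alphabet = tuple(str(s) for s in observed)
        entries = {t: frozenset({str(int(leaf_codes[t][j]))}) for t in leaf_order}
        columns.append(CharacterColumn(f"{id_prefix}{j + 1}", alphabet, entries, type_tag))
    meta = pd.DataFrame(
        {
            "id": [c.id for c in columns],
            "type": type_tag,
            "n_states_generating": N,
            "rate": r,
            "steps": steps,
            "n_states_observed": [len(c.alphabet) for c in columns],
            "constant": [len(c.alphabet) == 1 for c in columns],
        }
    )
    return columns, meta


def simulate_dataset(
    config: SimConfig, replicate: int = 0
) -> tuple[CharacterMatrix, pd.DataFrame]:
    """Simulate one replicate: a typed character matrix plus per-character
    metadata (generating state count, rate, realized substitution steps).

    Constant columns are retained but flagged; the standard informativeness
    filter removes them downstream.  Output is deterministic in
    ``(config.seed, replicate)``.
    """
    if not 0 <= replicate:
        raise ValueError("replicate must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, replicate)))
    morph_cols, morph_meta = _simulate_block(
        config.tree, config.morph_states, config.n_morph, config.rate_correlation,
        rng, MORPHOLOGICAL, "morph", config.steps_mode,
    )
    mol_cols, mol_meta = _simulate_block(
        config.tree, config.mol_states, config.n_mol, config.rate_correlation,
        rng, MOLECULAR, "mol", config.steps_mode,
    )
    taxa = [config.tree.labels[n] for n in config.tree.leaves()]
    matrix = CharacterMatrix(taxa, morph_cols + mol_cols)
    meta = pd.concat([morph_meta, mol_meta], ignore_index=True)
    return matrix, meta


def iter_replicates(config: SimConfig) -> Iterator[tuple[CharacterMatrix, pd.DataFrame]]:
    for rep in range(config.n_replicates):
        yield simulate_dataset(config, rep)
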