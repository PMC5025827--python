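# convergia

Parsimony-based quantification of evolutionary convergence on phylogenies,
with a character-evolution simulator and a low-convergence character
filtering pipeline for total-evidence tree inference.

The package compares morphological and molecular phylogenetic characters by
how often they evolve the same derived state on independent branches:

- **Whole-tree analysis** — Fitch–Hartigan ancestral reconstruction with
  exact uniform weighting over all most-parsimonious reconstructions
  (MPRs); weighted convergence (Cv) and divergence (Dv) tallies for every
  independent branch pair; ci/ri/rc homoplasy indices; Fisher exact tests
  with BH q-values and a character-bootstrap majority test.
- **Quartet analysis** — quartets congruent between two rooted trees;
  per-quartet and per-character convergence (Cv) and consistency (Cs)
  counts.
- **Simulator** — multistate characters evolving by an equal-exchange
  Markov model on a fixed 46-taxon reference tree, with per-character state
  counts drawn from configurable empirical profiles and rates correlated
  with state count (target Pearson r = 0.64, mean rate exactly 1).
- **Tree inference** — replicated random-addition maximum-parsimony search
  with SPR rearrangements (plus bounded TBR re-rooting), strict consensus,
  bootstrap support with the 1/k rule for ties, and normalized
  Robinson–Foulds distances.
- **Filtering pipeline** — per-character Cv/Cs from congruent quartets,
  cutoff sweeps, matched random-removal controls, and d_RF evaluation
  against a reference tree.

## Command line

```sh
convergia io validate matrix.nex
convergia io filter-informative matrix.nex informative.nex
convergia parsimony indices matrix.nex tree.nwk --out indices.tsv
convergia whole-tree matrix.nex tree.nwk --out-prefix whole_tree
convergia quartets matrix.nex tree_morph.nwk tree_mol.nwk
convergia stats fisher 25 3389 22 5700
convergia simulate --n-morph 2000 --n-mol 4000 --seed 1 --out-prefix sim
convergia tree search matrix.nex --reps 10 --seed 1 --out best.nwk
convergia tree rf a.nwk b.nwk
convergia filter run --matrix m.nex --tree-morph tm.nwk --tree-mol to.nwk \
    --seed 1 --out filter_out/
```

Matrix dialects: NEXUS (standard/protein/dna), TNT `xread`, FASTA, relaxed
PHYLIP. Missing entries (`?`, gaps) map to the full column alphabet;
`{..}`/`(..)` polymorphisms to the listed subset. Trees are Newick with
optional branch lengths and internal labels.

## Python API sketch

```python
from convergia import (
    read_character_matrix, read_newick, filter_parsimony_informative,
    MPRSummary, analyze_whole_tree, find_congruent_quartets, quartet_tally,
    SimConfig, simulate_dataset, heuristic_search, robinson_foulds,
    run_cutoff_sweep,
)

matrix = filter_parsimony_informative(read_character_matrix("m.nex", "nexus"))
tree = read_newick("tree.nwk")
pair_table, char_table = analyze_whole_tree(matrix, tree)
```
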