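"""Character matrices, rooted trees, and the file dialects that carry them.

Character data are held as *state sets*: a singleton set is an observed
state, the full column alphabet is a missing entry ("?" or an alignment
gap), and any other non-empty subset is a polymorphism.  Trees are rooted,
possibly multifurcating, with unique node ids and optional branch lengths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "CharacterColumn",
    "CharacterMatrix",
    "RootedTree",
    "MatrixParseError",
    "MORPHOLOGICAL",
    "MOLECULAR",
    "read_character_matrix",
    "write_character_matrix",
    "filter_parsimony_informative",
    "read_newick",
    "write_newick",
    "reconcile_taxa",
    "concatenate_matrices",
]

MORPHOLOGICAL = "morphological"
MOLECULAR = "molecular"

_PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
_DNA_ALPHABET = tuple("ACGT")


class MatrixParseError(ValueError):
    """Raised when a character-matrix or tree file cannot be parsed."""


# ---------------------------------------------------------------------------
# character matrix types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterColumn:
    """One character: a map from taxon to a non-empty state set."""

    id: str
    alphabet: tuple[str, ...]
    entries: Mapping[str, frozenset[str]]
    type_tag: str = MORPHOLOGICAL

    def __post_init__(self) -> None:
        alpha = frozenset(self.alphabet)
        for taxon, states in self.entries.items():
            if not states:
                raise ValueError(f"empty state set for taxon {taxon!r} in column {self.id!r}")
            if not states <= alpha:
                raise ValueError(
                    f"state set {sorted(states)} outside alphabet of column {self.id!r}"
                )

    def state_set(self, taxon: str) -> frozenset[str]:
        return self.entries[taxon]

    def is_missing(self, taxon: str) -> bool:
        return self.entries[taxon] == frozenset(self.alphabet)

    @property
    def observed_states(self) -> frozenset[str]:
        """States appearing as a singleton (unambiguous) entry."""
        return frozenset(next(iter(s)) for s in self.entries.values() if len(s) == 1)

    @property
    def observed_state_count(self) -> int:
        return len(self.observed_states)

    def state_support(self) -> dict[str, int]:
        """Number of taxa unambiguously carrying each state."""
        support: dict[str, int] = {}
        for states in self.entries.values():
            if len(states) == 1:
                (s,) = states
                support[s] = support.get(s, 0) + 1
        return support

    def is_parsimony_informative(self) -> bool:
        return sum(1 for n in self.state_support().values() if n >= 2) >= 2


@dataclass
class CharacterMatrix:
    """An ordered taxa-by-characters table of state sets."""

    taxa: list[str]
    columns: list[CharacterColumn]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixParseError(f"duplicate taxon labels: {dupes}")
        taxa = set(self.taxa)
        for col in self.columns:
            if set(col.entries) != taxa:
                raise ValueError(f"column {col.id!r} does not cover the matrix taxa exactly")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_ids(self) -> list[str]:
        return [c.id for c in self.columns]

    def columns_of_type(self, type_tag: str) -> list[CharacterColumn]:
        return [c for c in self.columns if c.type_tag == type_tag]

    def select_columns(self, ids: Iterable[str]) -> "CharacterMatrix":
        wanted = set(ids)
        return CharacterMatrix(list(self.taxa), [c for c in self.columns if c.id in wanted])

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        keep = [t for t in self.taxa if t in set(taxa)]
        cols = [
            CharacterColumn(
                c.id, c.alphabet, {t: c.entries[t] for t in keep}, c.type_tag
            )
            for c in self.columns
        ]
        return CharacterMatrix(keep, cols)


# ---------------------------------------------------------------------------
# rooted trees
# ---------------------------------------------------------------------------


class RootedTree:
    """A rooted (binary or multifurcating) tree with uniquely labelled nodes.

    Node ids are small integers.  Leaves carry taxon labels; internal nodes
    may carry labels too.  Branch lengths, when present, hang on the child
    node of each edge.
    """

    def __init__(self) -> None:
        self.root: int = 0
        self._children: dict[int, list[int]] = {0: []}
        self._parent: dict[int, int | None] = {0: None}
        self.labels: dict[int, str] = {}
        self.lengths: dict[int, float] = {}
        self._next_id = 1

    # -- construction -------------------------------------------------------

    def add_child(self, parent: int, label: str | None = None,
                  length: float | None = None) -> int:
        node = self._next_id
        self._next_id += 1
        self._children[node] = []
        self._children[parent].append(node)
        self._parent[node] = parent
        if label is not None:
            self.labels[node] = label
        if length is not None:
            if length < 0:
                raise ValueError(f"negative branch length {length} on node {node}")
            self.lengths[node] = length
        return node

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        try:
            dtree = dendropy.Tree.get(
                data=text if text.strip().endswith(";") else text + ";",
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise MatrixParseError(f"cannot parse newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "RootedTree":
        tree = cls()
        stack = [(dtree.seed_node, tree.root)]
        if dtree.seed_node.taxon is not None:
            tree.labels[tree.root] = dtree.seed_node.taxon.label
        elif dtree.seed_node.label:
            tree.labels[tree.root] = dtree.seed_node.label
        while stack:
            dnode, nid = stack.pop()
            for child in dnode.child_nodes():
                label = None
                if child.taxon is not None:
                    label = child.taxon.label
                elif child.label:
                    label = child.label
                cid = tree.add_child(nid, label=label, length=child.edge.length)
                stack.append((child, cid))
        labels = [tree.labels[n] for n in tree.leaves()]
        if len(set(labels)) != len(labels):
            raise MatrixParseError("duplicate leaf labels in tree")
        return tree

    def copy(self) -> "RootedTree":
        out = RootedTree.__new__(RootedTree)
        out.root = self.root
        out._children = {n: list(c) for n, c in self._children.items()}
        out._parent = dict(self._parent)
        out.labels = dict(self.labels)
        out.lengths = dict(self.lengths)
        out._next_id = self._next_id
        return out

    # -- structure queries --------------------------------------------------

    def nodes(self) -> list[int]:
        return list(self._children)

    def children(self, node: int) -> tuple[int, ...]:
        return tuple(self._children[node])

    def parent(self, node: int) -> int | None:
        return self._parent[node]

    def is_leaf(self, node: int) -> bool:
        return not self._children[node]

    def leaves(self) -> list[int]:
        return [n for n in self.postorder() if self.is_leaf(n)]

    def leaf_labels(self) -> list[str]:
        return [self.labels[n] for n in self.leaves()]

    def label(self, node: int) -> str | None:
        return self.labels.get(node)

    def node_of(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise KeyError(label)

    def length(self, node: int) -> float | None:
        return self.lengths.get(node)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self._children[node]:
                    stack.append((c, False))
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self._children[node]))
        return order

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) edges."""
        return [(self._parent[n], n) for n in self.preorder() if n != self.root]

    def ancestors(self, node: int) -> set[int]:
        """Strict ancestors of *node* (root included, node excluded)."""
        out = set()
        p = self._parent[node]
        while p is not None:
            out.add(p)
            p = self._parent[p]
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if *a* is a strict ancestor of *b*."""
        return a in self.ancestors(b)

    def mrca(self, nodes: Iterable[int]) -> int:
        nodes = list(nodes)
        common: set[int] | None = None
        for n in nodes:
            anc = self.ancestors(n) | {n}
            common = anc if common is None else common & anc
        assert common
        # deepest common ancestor
        depth = {n: len(self.ancestors(n)) for n in common}
        return max(common, key=lambda n: depth[n])

    def clade_leaf_labels(self, node: int) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.append(self.labels[n])
            else:
                stack.extend(self._children[n])
        return frozenset(out)

    # -- output -------------------------------------------------------------

    def newick(self) -> str:
        def fmt(node: int) -> str:
            lab = self.labels.get(node, "")
            if any(ch in lab for ch in " ()[]{}:;,"):
                lab = "'" + lab.replace("'", "''") + "'"
            if not self.is_leaf(node):
                inner = ",".join(fmt(c) for c in self._children[node])
                lab = f"({inner}){lab}"
            if node in self.lengths:
                lab += f":{self.lengths[node]:g}"
            return lab

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<RootedTree {len(self.leaves())} leaves>"


def read_newick(source: str | Path) -> RootedTree:
    """Read one rooted tree from a newick file path or literal string."""
    text = _slurp(source)
    return RootedTree.from_newick(text)


def write_newick(tree: RootedTree, path: str | Path | None = None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _slurp(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "(" in s or "\n" in s or ">" in s or "#" in s:
        return s
    p = Path(s)
    if p.exists():
        return p.read_text()
    return s


# ---------------------------------------------------------------------------
# matrix readers
# ---------------------------------------------------------------------------


def read_character_matrix(
    path: str | Path,
    dialect: str,
    *,
    type_tag: str | None = None,
    datatype: str = "auto",
    id_prefix: str | None = None,
) -> CharacterMatrix:
    """Read a character matrix in one of the supported dialects.

    Parameters
    ----------
    dialect
        One of ``nexus``, ``tnt``, ``fasta``, ``phylip``.
    type_tag
        Override the per-column character-type tag; defaults to
        ``morphological`` for standard (integer-coded) data and
        ``molecular`` for sequence data.
    datatype
        For sequence dialects: ``auto``, ``dna``, ``protein`` or
        ``standard``.
    """
    dialect = dialect.lower()
    text = _read_text(path)
    if dialect == "tnt":
        return _read_tnt(text, type_tag or MORPHOLOGICAL, id_prefix)
    if dialect == "nexus":
        return _read_dendropy(text, "nexus", type_tag, datatype, id_prefix)
    if dialect in ("fasta", "phylip"):
        return _read_dendropy(text, dialect, type_tag, datatype, id_prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_text(path: str | Path) -> str:
    p = Path(path)
    if p.exists():
        return p.read_text()
    s = str(path)
    if "\n" in s:
        return s
    raise FileNotFoundError(path)


def _guess_molecular_datatype(text: str, schema: str) -> str:
    seq_chars = set()
    for line in text.splitlines():
        if schema == "fasta" and line.startswith(">"):
            continue
        seq_chars.update(line.strip().upper())
    residues = seq_chars & set("ABCDEFGHIKLMNPQRSTVWYZ")
    return "dna" if residues <= set("ACGTUN") else "protein"


def _read_dendropy(
    text: str, schema: str, type_tag: str | None, datatype: str, id_prefix: str | None
) -> CharacterMatrix:
    if schema == "nexus":
        try:
            ds = dendropy.DataSet.get(data=text, schema="nexus")
        except Exception as exc:
            raise MatrixParseError(f"cannot parse NEXUS: {exc}") from exc
        if not ds.char_matrices:
            raise MatrixParseError("NEXUS file contains no character matrix")
        dmat = ds.char_matrices[0]
    else:
        if datatype == "auto":
            datatype = _guess_molecular_datatype(text, schema)
        cls = {
            "dna": dendropy.DnaCharacterMatrix,
            "protein": dendropy.ProteinCharacterMatrix,
            "standard": dendropy.StandardCharacterMatrix,
        }[datatype]
        try:
            dmat = cls.get(data=text, schema=schema)
        except Exception as exc:
            raise MatrixParseError(f"cannot parse {schema}: {exc}") from exc
    return _from_dendropy_matrix(dmat, type_tag, id_prefix)


def _from_dendropy_matrix(
    dmat: dendropy.CharacterMatrix, type_tag: str | None, id_prefix: str | None
) -> CharacterMatrix:
    if isinstance(dmat, dendropy.DnaCharacterMatrix):
        base_alpha: tuple[str, ...] | None = _DNA_ALPHABET
        tag = type_tag or MOLECULAR
    elif isinstance(dmat, dendropy.ProteinCharacterMatrix):
        base_alpha = _PROTEIN_ALPHABET
        tag = type_tag or MOLECULAR
    else:
        base_alpha = None  # per-column, observed symbols only
        tag = type_tag or MORPHOLOGICAL

    taxa = [t.label for t in dmat.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise MatrixParseError("duplicate taxon labels")
    seqs = {t.label: dmat[t] for t in dmat.taxon_namespace}
    lengths = {len(v) for v in seqs.values()}
    if len(lengths) != 1:
        raise MatrixParseError(f"unequal sequence lengths: {sorted(lengths)}")
    (n_char,) = lengths

    prefix = id_prefix if id_prefix is not None else ("mol" if tag == MOLECULAR else "morph")
    columns = []
    for j in range(n_char):
        raw: dict[str, frozenset[str] | None] = {}
        observed: set[str] = set()
        for taxon in taxa:
            state = seqs[taxon][j]
            symbols = frozenset(
                s.symbol for s in state.fundamental_states if s.symbol not in ("?", "-")
            )
            if state.symbol in ("?", "-") or not symbols:
                raw[taxon] = None  # missing -> full alphabet, resolved below
            else:
                if base_alpha is not None and not symbols <= set(base_alpha):
                    raw[taxon] = None  # non-standard residue treated as missing
                else:
                    raw[taxon] = symbols
                    observed.update(symbols)
        if base_alpha is not None:
            alphabet = base_alpha
        else:
            alphabet = tuple(sorted(observed)) if observed else ("0",)
        full = frozenset(alphabet)
        entries = {t: (full if v is None else v) for t, v in raw.items()}
        columns.append(CharacterColumn(f"{prefix}{j + 1}", alphabet, entries, tag))
    return CharacterMatrix(taxa, columns)


_TNT_TOKEN = re.compile(r"\{[^}]*\}|\([^)]*\)|\[[^\]]*\]|\S")


def _read_tnt(text: str, type_tag: str, id_prefix: str | None) -> CharacterMatrix:
    """Minimal reader for the TNT ``xread`` matrix dialect."""
    body = re.sub(r"'[^']*'", " ", text)  # strip quoted comments
    m = re.search(r"xread\s+(\d+)\s+(\d+)(.*?);", body, re.S | re.I)
    if not m:
        raise MatrixParseError("no 'xread <nchar> <ntax> ... ;' block found")
    n_char, n_tax = int(m.group(1)), int(m.group(2))
    rows: dict[str, list[frozenset[str] | None]] = {}
    taxa: list[str] = []
    for lineno, line in enumerate(m.group(3).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        name, _, states = line.partition(" ")
        if not states.strip():
            raise MatrixParseError(f"TNT row {lineno}: missing states for {name!r}")
        if name in rows:
            raise MatrixParseError(f"duplicate taxon label {name!r}")
        cells: list[frozenset[str] | None] = []
        for tok in _TNT_TOKEN.findall(states.strip()):
            if tok[0] in "{([":
                cells.append(frozenset(tok[1:-1]))
            elif tok in ("?", "-"):
                cells.append(None)
            else:
                cells.append(frozenset(tok))
        if len(cells) != n_char:
            raise MatrixParseError(
                f"TNT row {lineno} ({name!r}): {len(cells)} states, expected {n_char}"
            )
        rows[name] = cells
        taxa.append(name)
    if len(taxa) != n_tax:
        raise MatrixParseError(f"TNT: {len(taxa)} taxa found, header says {n_tax}")
    prefix = id_prefix or "morph"
    columns = []
    for j in range(n_char):
        observed: set[str] = set()
        for t in taxa:
            cell = rows[t][j]
            if cell is not None:
                observed.update(cell)
        alphabet = tuple(sorted(observed)) if observed else ("0",)
        full = frozenset(alphabet)
        entries = {t: (full if rows[t][j] is None else rows[t][j]) for t in taxa}
        columns.append(CharacterColumn(f"{prefix}{j + 1}", alphabet, entries, type_tag))
    return CharacterMatrix(taxa, columns)


def write_character_matrix(
    matrix: CharacterMatrix, path: str | Path | None = None
) -> str:
    """Serialize a matrix as a NEXUS standard-characters block.

    Missing entries (full-alphabet state sets) are written as ``?`` and
    polymorphisms as ``{..}``; state sets round-trip exactly.  Type tags are
    not stored in the file and must be re-supplied on reading.
    """
    symbols = sorted({s for c in matrix.columns for s in c.alphabet})
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_columns};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{"".join(symbols)}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for taxon in matrix.taxa:
        cells = []
        for col in matrix.columns:
            states = col.entries[taxon]
            if states == frozenset(col.alphabet):
                cells.append("?")
            elif len(states) == 1:
                cells.append(next(iter(states)))
            else:
                cells.append("{" + "".join(sorted(states)) + "}")
        safe = taxon if " " not in taxon else f"'{taxon}'"
        lines.append(f"{safe} {''.join(cells)}")
    lines += [";", "END;", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# filtering and reconciliation
# ---------------------------------------------------------------------------


def filter_parsimony_informative(
    matrix: CharacterMatrix, return_removed: bool = False
):
    """Keep columns with >=2 states, each carried unambiguously by >=2 taxa.

    Ambiguous entries (missing or polymorphic) support no state.
    """
    kept, removed = [], []
    for col in matrix.columns:
        (kept if col.is_parsimony_informative() else removed).append(col)
    out = CharacterMatrix(list(matrix.taxa), kept)
    if return_removed:
        return out, [c.id for c in removed]
    return out


def reconcile_taxa(matrix: CharacterMatrix, tree: RootedTree) -> CharacterMatrix:
    """Restrict a matrix to a tree's leaf set, padding absent taxa as missing.

    Analyses run on the tree's leaves: matrix taxa not in the tree are
    dropped, and tree leaves without data (e.g. fossils in a molecular
    block) get all-missing entries.
    """
    tree_taxa = tree.leaf_labels()
    cols = []
    for col in matrix.columns:
        full = frozenset(col.alphabet)
        entries = {t: col.entries.get(t, full) for t in tree_taxa}
        cols.append(CharacterColumn(col.id, col.alphabet, entries, col.type_tag))
    return CharacterMatrix(list(tree_taxa), cols)


def concatenate_matrices(*matrices: CharacterMatrix) -> CharacterMatrix:
    """Concatenate character blocks over the union of their taxa.

    Taxa absent from one block get all-missing entries for its columns,
    which is the total-evidence convention for e.g. fossils without
    molecular data.
    """
    taxa: list[str] = []
    for m in matrices:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    cols = []
    seen_ids: set[str] = set()
    for m in matrices:
        for col in m.columns:
            cid = col.id
            while cid in seen_ids:
                cid += "'"
            seen_ids.add(cid)
            full = frozenset(col.alphabet)
            entries = {t: col.entries.get(t, full) for t in taxa}
            cols.append(CharacterColumn(cid, col.alphabet, entries, col.type_tag))
    return CharacterMatrix(taxa, cols)
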