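import numpy as np
import pytest

from convergia.matrix_io import (
    CharacterColumn,
    CharacterMatrix,
    MatrixParseError,
    RootedTree,
    concatenate_matrices,
    filter_parsimony_informative,
    read_character_matrix,
    read_newick,
    reconcile_taxa,
    write_character_matrix,
    write_newick,
)
from convergia.char_evolution_simulator import DEFAULT_TREE_NEWICK

from conftest import make_column, random_column, random_rooted_tree

NEXUS_SMALL = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=1;
FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
MATRIX
t1 0
t2 1
t3 ?
t4 {01}
;
END;
"""


class TestReadCharacterMatrix:
    def test_nexus_states_missing_polymorphism(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_SMALL)
        m = read_character_matrix(p, "nexus")
        col = m.columns[0]
        assert m.taxa == ["t1", "t2", "t3", "t4"]
        assert col.entries["t1"] == frozenset("0")
        assert col.entries["t2"] == frozenset("1")
        assert col.entries["t3"] == frozenset("01")  # missing -> full alphabet
        assert col.entries["t4"] == frozenset("01")  # listed subset
        assert col.type_tag == "morphological"

    def test_fasta_identical_sequences(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAC\n>s2\nAC\n")
        m = read_character_matrix(p, "fasta", datatype="protein")
        assert m.n_columns == 2
        for col in m.columns:
            assert col.entries["s1"] == col.entries["s2"]
            assert len(col.entries["s1"]) == 1
        assert m.columns[0].type_tag == "molecular"
        assert len(m.columns[0].alphabet) == 20

    def test_tnt_three_state_alphabet(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread 2 4\nta 00\ntb 11\ntc 22\ntd 0{12}\n;\n")
        m = read_character_matrix(p, "tnt")
        col = m.columns[0]
        assert col.alphabet == ("0", "1", "2")
        expected = CharacterColumn(
            "morph1",
            ("0", "1", "2"),
            {
                "ta": frozenset("0"),
                "tb": frozenset("1"),
                "tc": frozenset("2"),
                "td": frozenset("0"),
            },
        )
        assert col.entries == expected.entries
        assert m.columns[1].entries["td"] == frozenset("12")

    def test_gap_maps_to_full_alphabet(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nA-\n>s2\nAC\n")
        m = read_character_matrix(p, "fasta", datatype="dna")
        assert m.columns[1].entries["s1"] == frozenset("ACGT")

    def test_duplicate_taxon_errors(self, tmp_path):
        p = tmp_path / "m.tnt"
        p.write_text("xread 1 2\nta 0\nta 1\n;\n")
        with pytest.raises(MatrixParseError):
            read_character_matrix(p, "tnt")

    def test_malformed_file_errors(self, tmp_path):
        p = tmp_path / "bad.nex"
        p.write_text("#NEXUS\nBEGIN DATA;\ngarbage")
        with pytest.raises(MatrixParseError):
            read_character_matrix(p, "nexus")

    def test_matrix_roundtrip_preserves_state_sets(self, tmp_path):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(6)]
        cols = [
            random_column(taxa, rng, max_states=4, p_missing=0.2, p_poly=0.2,
                          col_id=f"c{j}")
            for j in range(20)
        ]
        m = CharacterMatrix(taxa, cols)
        p1, p2 = tmp_path / "r1.nex", tmp_path / "r2.nex"
        write_character_matrix(m, p1)
        once = read_character_matrix(p1, "nexus")
        write_character_matrix(once, p2)
        twice = read_character_matrix(p2, "nexus")
        # read -> write is a fixpoint: state sets are preserved exactly
        assert p1.read_text() == p2.read_text()
        for a, b in zip(once.columns, twice.columns):
            assert {t: a.entries[t] for t in taxa} == {t: b.entries[t] for t in taxa}
        # and columns whose alphabet states are all observed survive verbatim
        for orig, new in zip(m.columns, once.columns):
            if orig.observed_states == set(orig.alphabet):
                assert {t: orig.entries[t] for t in taxa} == {
                    t: new.entries[t] for t in taxa
                }


class TestFilterParsimonyInformative:
    @pytest.mark.parametrize(
        "states,kept",
        [
            (["A", "A", "B", "B"], True),
            (["A", "A", "A", "B"], False),
            (["A", "A", "B", "?"], False),  # '?' supports no state
        ],
    )
    def test_informativeness_rules(self, states, kept):
        taxa = ["t1", "t2", "t3", "t4"]
        col = make_column(taxa, states)
        m = CharacterMatrix(taxa, [col])
        out, removed = filter_parsimony_informative(m, return_removed=True)
        assert (out.n_columns == 1) is kept
        assert (removed == []) is kept

    def test_polymorphic_entries_support_no_state(self):
        taxa = ["t1", "t2", "t3", "t4"]
        col = make_column(taxa, ["A", "A", "B", "AB"])
        m = CharacterMatrix(taxa, [col])
        assert filter_parsimony_informative(m).n_columns == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(5)]
        cols = [
            random_column(taxa, rng, p_missing=0.3, col_id=f"c{j}")
            for j in range(30)
        ]
        m = CharacterMatrix(taxa, cols)
        once = filter_parsimony_informative(m)
        twice = filter_parsimony_informative(once)
        assert once.column_ids() == twice.column_ids()


class TestNewick:
    def test_two_cherries(self):
        t = read_newick("((A,B),(C,D));")
        assert sorted(t.leaf_labels()) == ["A", "B", "C", "D"]
        kids = t.children(t.root)
        assert len(kids) == 2
        assert all(len(t.children(k)) == 2 for k in kids)

    def test_full_reference_tree(self):
        t = read_newick(DEFAULT_TREE_NEWICK)
        assert len(t.leaves()) == 46
        internal = [n for n in t.nodes() if not t.is_leaf(n)]
        assert len(internal) == 45
        # branch lengths preserved to printed precision
        n2 = t.node_of("2")
        assert t.length(n2) == pytest.approx(0.0568)

    def test_roundtrip_identity(self):
        s = "((A:1,B:2):0.5,(C:1,(D:2,E:3):1):0.5);"
        t = read_newick(s)
        assert write_newick(t) == s

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(MatrixParseError):
            read_newick("((A,B),(C,D);")

    def test_random_roundtrip_topology(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(7)]
        t = random_rooted_tree(labels, rng)
        back = read_newick(write_newick(t))
        def clades(tr):
            return {tr.clade_leaf_labels(n) for n in tr.nodes()}
        assert clades(t) == clades(back)


class TestReconcileAndConcat:
    def test_reconcile_pads_missing_taxa(self):
        taxa = ["A", "B", "C"]
        col = make_column(taxa, ["0", "1", "0"])
        m = CharacterMatrix(taxa, [col])
        tree = read_newick("((A,B),(C,D));")
        out = reconcile_taxa(m, tree)
        assert set(out.taxa) == {"A", "B", "C", "D"}
        assert out.columns[0].entries["D"] == frozenset(col.alphabet)

    def test_concatenate_total_evidence(self):
        morph = CharacterMatrix(
            ["A", "B", "Fossil"],
            [make_column(["A", "B", "Fossil"], ["0", "1", "0"], col_id="m1")],
        )
        mol = CharacterMatrix(
            ["A", "B"],
            [make_column(["A", "B"], ["C", "G"], col_id="s1",
                         type_tag="molecular")],
        )
        both = concatenate_matrices(morph, mol)
        assert both.n_taxa == 3
        assert both.n_columns == 2
        mol_col = both.columns[1]
        assert mol_col.entries["Fossil"] == frozenset(mol_col.alphabet)
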