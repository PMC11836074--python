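"""Lexicon reading, IPA tokenization, ARPABET conversion, adjlist round-trips."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from phononet.lexicon import (
    DuplicateWordError,
    PhonemeInventory,
    TokenizationError,
    arpabet_to_ipa,
    default_inventory,
    read_adjlist,
    read_cmu_dict,
    read_lexicon,
    tokenize_ipa,
    write_adjlist,
    write_lexicon,
)


class TestTokenizeIPA:
    @pytest.mark.parametrize(
        "ipa,expected",
        [
            ("kæt", ("k", "æ", "t")),
            ("tʃɪn", ("tʃ", "ɪ", "n")),  # affricate is one token
            ("dɪspɹuvən", ("d", "ɪ", "s", "p", "ɹ", "u", "v", "ə", "n")),
            ("ˈkæt", ("k", "æ", "t")),  # stress mark stripped
            ("boʊt", ("b", "oʊ", "t")),  # diphthong beats 'o' by longest match
            ("bɝd", ("b", "ɝ", "d")),
        ],
    )
    def test_segmentation(self, ipa, expected):
        assert tokenize_ipa(ipa) == expected

    def test_unknown_character_names_position(self):
        with pytest.raises(TokenizationError, match=r"'%'.*position 2"):
            tokenize_ipa("kæ%t")

    def test_empty_rejected(self):
        with pytest.raises(TokenizationError):
            tokenize_ipa("")

    @given(st.lists(st.sampled_from(sorted(default_inventory().tokens)),
                    min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_concatenation_roundtrip(self, tokens):
        """Concatenating the returned tokens reconstructs the input string."""
        s = "".join(tokens)
        out = tokenize_ipa(s)
        assert "".join(out) == s

    def test_longest_match_independent_of_inventory_order(self):
        inv1 = PhonemeInventory(frozenset(["t", "ʃ", "tʃ", "ɪ", "n"]))
        inv2 = PhonemeInventory(frozenset(["tʃ", "ɪ", "ʃ", "n", "t"]))
        assert tokenize_ipa("tʃɪn", inv1) == tokenize_ipa("tʃɪn", inv2) == ("tʃ", "ɪ", "n")

    def test_ignorable_cannot_be_token(self):
        with pytest.raises(ValueError):
            PhonemeInventory(frozenset(["a", "ˈ"]), ignorable=frozenset(["ˈ"]))


class TestArpabet:
    @pytest.mark.parametrize(
        "arp,expected",
        [
            (["K", "AE1", "T"], ("k", "æ", "t")),
            (["CH", "IH0", "N"], ("tʃ", "ɪ", "n")),
            (["ER0"], ("ɝ",)),  # rhotic vowel is a single token
        ],
    )
    def test_mapping(self, arp, expected):
        assert arpabet_to_ipa(arp) == expected

    def test_length_preserved(self):
        arp = ["B", "OY1", "Z"]
        assert len(arpabet_to_ipa(arp)) == len(arp)

    def test_unknown_symbol(self):
        with pytest.raises(ValueError, match="QX"):
            arpabet_to_ipa(["QX"])

    def test_output_tokenizes_under_default_inventory(self):
        from phononet.lexicon import ARPABET_TO_IPA

        inv = default_inventory()
        for ipa in ARPABET_TO_IPA.values():
            assert ipa in inv.tokens

    def test_cmu_dict_file(self, tmp_path):
        p = tmp_path / "cmu.txt"
        p.write_text(
            ";;; comment\nCAT  K AE1 T\nCAT(1)  K AA1 T\nCHIN  CH IH1 N\n",
            encoding="utf-8",
        )
        d = read_cmu_dict(p)
        assert d == {"cat": ("k", "æ", "t"), "chin": ("tʃ", "ɪ", "n")}


class TestReadLexicon:
    def _write(self, tmp_path, rows, header="Word\tIPA\tFREQcount\tLemma\tPOS"):
        p = tmp_path / "lex.tsv"
        p.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")
        return p

    def test_basic_parse(self, tmp_path):
        p = self._write(tmp_path, ["cat\tkæt\t100\t\t", "cats\tkæts\t40\tcat\t",
                                   "dog\tdɔg\t80\t\t"])
        lex, report = read_lexicon(p)
        assert len(lex) == 3
        assert lex.inventory == {"k", "æ", "t", "s", "d", "ɔ", "g"}
        assert lex["cats"].lemma == "cat"
        assert lex["cat"].lemma is None
        assert report.n_skipped == 0

    def test_duplicate_word_names_both_rows(self, tmp_path):
        p = self._write(tmp_path, ["cat\tkæt\t100\t\t", "cat\tkɑt\t5\t\t"])
        with pytest.raises(DuplicateWordError, match=r"rows 2 and 3"):
            read_lexicon(p)

    def test_empty_rows_skipped_and_counted(self, tmp_path):
        p = self._write(tmp_path, ["cat\tkæt\t100\t\t", "\tkɑt\t5\t\t", "dog\t\t1\t\t"])
        lex, report = read_lexicon(p)
        assert len(lex) == 1
        assert report.skipped_rows == [3, 4]

    def test_missing_column(self, tmp_path):
        p = self._write(tmp_path, ["cat\t100"], header="Word\tFREQcount")
        with pytest.raises(KeyError, match="IPA"):
            read_lexicon(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_lexicon(tmp_path / "nope.tsv")

    def test_column_map(self, tmp_path):
        p = self._write(tmp_path, ["cat,kæt,7"], header="w,t,f")
        lex, _ = read_lexicon(p, column_map={"word": "w", "ipa": "t", "frequency": "f"},
                              delimiter=",")
        assert lex["cat"].frequency == 7.0

    def test_write_read_roundtrip(self, tmp_path, tiny_lex):
        p = tmp_path / "out.tsv"
        write_lexicon(tiny_lex, p)
        back, _ = read_lexicon(p)
        assert back.words() == tiny_lex.words()
        assert all(back[w].phonemes == tiny_lex[w].phonemes for w in back.words())


class TestAdjlist:
    def test_triangle_roundtrip(self, tmp_path):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        path = tmp_path / "tri.adjlist"
        write_adjlist(g, path)
        lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        assert len(lines) == 3
        mentions = sum(len(ln.split()) - 1 for ln in lines)
        assert mentions == 3  # each edge serialized exactly once
        back = read_adjlist(path)
        assert set(back.nodes) == set(g.nodes) and set(map(frozenset, back.edges)) == set(
            map(frozenset, g.edges)
        )

    def test_isolate_survives(self, tmp_path):
        g = nx.Graph([("a", "b")])
        g.add_node("z")
        path = tmp_path / "iso.adjlist"
        write_adjlist(g, path)
        back = read_adjlist(path)
        assert "z" in back.nodes and back.degree("z") == 0

    def test_self_loop_rejected(self, tmp_path):
        path = tmp_path / "loop.adjlist"
        path.write_text("a a b\nb\n")
        with pytest.raises(ValueError, match="self-loop"):
            read_adjlist(path)

    def test_bad_node_key_rejected(self, tmp_path):
        g = nx.Graph()
        g.add_node("#bad")
        with pytest.raises(ValueError, match="'#'"):
            write_adjlist(g, tmp_path / "x.adjlist")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_graph_roundtrip(self, seed):
        """Node and edge sets survive serialization for arbitrary graphs."""
        import tempfile
        from pathlib import Path

        g = nx.gnp_random_graph(100, 0.03, seed=seed)
        g = nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "g.adjlist"
            write_adjlist(g, path)
            back = read_adjlist(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
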