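"""Neighbor predicate, indexed construction vs brute force, inflection filter."""

import pytest
from hypothesis import given, settings, strategies as st

from phononet import build_lemma_lexicon, build_network, inflection_filter, is_neighbor
from phononet.graphs import brute_force_edges
from phononet.lexicon import LexicalEntry, Lexicon

from conftest import synth_lexicon


class TestIsNeighbor:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("k", "æ", "t"), ("k", "æ", "t", "s"), True),  # addition
            (("k", "æ", "t"), ("k", "ɑ", "t"), True),  # substitution
            (("k", "æ", "t", "s"), ("k", "æ", "t"), True),  # deletion
            (("k", "æ", "t"), ("k", "æ", "t"), False),  # distance 0
            (("k", "æ", "t"), ("s", "k", "æ", "t", "s"), False),  # distance 2
            (("a", "b"), ("b", "a"), False),  # transposition is two edits
            (("a",), ("b", "c", "d"), False),
        ],
    )
    def test_cases(self, a, b, expected):
        assert is_neighbor(a, b) is expected

    @given(
        st.lists(st.sampled_from("abcd"), min_size=1, max_size=6),
        st.lists(st.sampled_from("abcd"), min_size=1, max_size=6),
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetry_and_edlib_agreement(self, a, b):
        """Symmetric, and equal to (edit distance == 1) from an independent
        alignment library."""
        import edlib

        assert is_neighbor(a, b) == is_neighbor(b, a)
        dist = edlib.align("".join(a), "".join(b), task="distance")["editDistance"]
        assert is_neighbor(a, b) == (dist == 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            is_neighbor((), ("a",))


class TestBuildNetwork:
    def test_tiny_edge_set_matches_oracle(self, tiny_lex, tiny_net):
        assert {frozenset(e) for e in tiny_net.edges} == brute_force_edges(tiny_lex)

    def test_hand_example(self):
        lex = Lexicon([
            LexicalEntry("cat", ("k", "æ", "t")),
            LexicalEntry("cats", ("k", "æ", "t", "s")),
            LexicalEntry("cot", ("k", "ɑ", "t")),
            LexicalEntry("scat", ("s", "k", "æ", "t")),
            LexicalEntry("dog", ("d", "ɔ", "g")),
        ])
        g = build_network(lex)
        # cats-scat is NOT an edge: [kæts] vs [skæt] needs two edits
        assert {frozenset(e) for e in g.edges} == {
            frozenset(("cat", "cats")), frozenset(("cat", "cot")),
            frozenset(("cat", "scat")),
        }
        assert g.degree("dog") == 0  # hermit retained

    def test_single_entry(self):
        g = build_network(Lexicon([LexicalEntry("a", ("æ",))]))
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_homophones_not_linked_but_share_neighbors(self):
        lex = Lexicon([
            LexicalEntry("sea", ("s", "i")),
            LexicalEntry("see", ("s", "i")),
            LexicalEntry("tea", ("t", "i")),
        ])
        g = build_network(lex)
        assert not g.has_edge("sea", "see")
        assert set(g.neighbors("sea")) == set(g.neighbors("see")) == {"tea"}

    @pytest.mark.parametrize("seed", range(10))
    def test_index_equals_brute_force(self, seed):
        """Deletion-key indexed construction is edge-equivalent to the
        all-pairs oracle on random synthetic lexicons."""
        n = 50 + (seed * 37) % 450
        lex = synth_lexicon(n_lemmas=n, seed=seed)
        g = build_network(lex)
        assert {frozenset(e) for e in g.edges} == brute_force_edges(lex)

    def test_index_equals_brute_force_large(self):
        lex = synth_lexicon(n_lemmas=1300, seed=99)  # ~2000 word forms
        g = build_network(lex)
        assert {frozenset(e) for e in g.edges} == brute_force_edges(lex)


class TestInflectionFilter:
    def test_same_lemma_edges_removed_nodes_kept(self, tiny_net):
        filtered, report = inflection_filter(tiny_net)
        assert set(filtered.nodes) == set(tiny_net.nodes)
        assert ("cat", "cats") in report.removed_edges or ("cats", "cat") in report.removed_edges
        assert not filtered.has_edge("cat", "cats")
        assert not filtered.has_edge("dog", "dogs")
        assert filtered.has_edge("cat", "cot")  # different lemmas kept

    def test_idempotent(self, tiny_net):
        once, r1 = inflection_filter(tiny_net)
        twice, r2 = inflection_filter(once)
        assert set(map(frozenset, once.edges)) == set(map(frozenset, twice.edges))
        assert r2.n_removed == 0

    def test_custom_predicate(self, tiny_net):
        keep_all, report = inflection_filter(tiny_net, same_family=lambda a, b: False)
        assert report.n_removed == 0
        assert keep_all.number_of_edges() == tiny_net.number_of_edges()


class TestBuildLemmaLexicon:
    def test_family_collapses_to_lemma_form(self):
        lex = Lexicon([
            LexicalEntry("cat", ("k", "æ", "t"), 100.0, lemma="cat"),
            LexicalEntry("cats", ("k", "æ", "t", "s"), 40.0, lemma="cat"),
        ])
        out, borrowed = build_lemma_lexicon(lex)
        assert len(out) == 1
        e = out["cat"]
        assert e.phonemes == ("k", "æ", "t") and e.frequency == 140.0
        assert borrowed == []

    def test_all_lemma_lexicon_is_identity(self, tiny_lex):
        base = Lexicon([e for e in tiny_lex if e.word == e.lemma])
        out, borrowed = build_lemma_lexicon(base)
        assert sorted(out.words()) == sorted(base.words())
        assert all(out[w].frequency == base[w].frequency for w in base.words())
        assert borrowed == []

    def test_missing_lemma_form_borrows_most_frequent(self):
        lex = Lexicon([
            LexicalEntry("goes", ("g", "oʊ", "z"), 50.0, lemma="go"),
            LexicalEntry("went", ("w", "ɛ", "n", "t"), 80.0, lemma="go"),
            LexicalEntry("going", ("g", "oʊ", "ɪ", "ŋ"), 60.0, lemma="go"),
        ])
        out, borrowed = build_lemma_lexicon(lex)
        assert out["go"].phonemes == ("w", "ɛ", "n", "t")  # highest frequency
        assert out["go"].frequency == 190.0
        assert borrowed == ["go"]
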