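"""Phonological similarity network construction.

Two words are phonological neighbors when their phoneme sequences differ by
exactly one substitution, addition, or deletion (token-level Levenshtein
distance 1, unit costs, no transposition). The network has one node per word
form — including words with no neighbors ("hermits") — and an edge for every
neighbor pair.

Construction uses a deletion-key index rather than all-pairs comparison:
every sequence is bucketed under its exact key and under each of its
delete-one-position keys; any distance-1 pair necessarily shares a bucket
(deletion/addition pairs share exact-vs-deleted keys, substitution pairs
share the key obtained by deleting the differing position). Bucket co-members
are then verified with an exact distance-1 check, so the index can only be
as permissive as, never different from, the brute-force edge set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx

from .lexicon import LexicalEntry, Lexicon

__all__ = [
    "is_neighbor", "build_network", "brute_force_edges",
    "inflection_filter", "InflectionReport", "build_lemma_lexicon",
]


def is_neighbor(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff the token-level Levenshtein distance of ``a`` and ``b`` is 1.

    Distance exactly 1 can only arise from a single substitution (equal
    lengths, one mismatching position) or a single insertion/deletion
    (lengths differing by one, alignable with a single skip), so no dynamic
    program is needed.
    """
    if not a or not b:
        raise ValueError("phoneme sequences must be nonempty")
    la, lb = len(a), len(b)
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if abs(la - lb) != 1:
        return False
    if la > lb:  # a is the longer sequence
        a, b = b, a
        la, lb = lb, la
    # b = a with one token inserted
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return tuple(a[i:]) == tuple(b[i + 1 :])


def _deletion_keys(seq: tuple[str, ...]):
    for i in range(len(seq)):
        yield seq[:i] + seq[i + 1 :]


def build_network(lexicon: Lexicon) -> nx.Graph:
    """Build the phonological similarity network of a lexicon.

    Nodes are word keys carrying ``phonemes``, ``frequency``, ``lemma`` and
    ``length`` attributes; edges link phonological neighbors. Words with
    identical transcriptions (homophones) are distinct nodes at distance 0
    and are never linked, though they share all neighbors.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    g = nx.Graph()
    for e in lexicon:
        g.add_node(
            e.word,
            phonemes=e.phonemes,
            frequency=e.frequency,
            lemma=e.lemma if e.lemma is not None else e.word,
            length=e.length,
        )

    buckets: dict[tuple[str, ...], list[int]] = defaultdict(list)
    entries = lexicon.entries
    for idx, e in enumerate(entries):
        buckets[e.phonemes].append(idx)
        for key in _deletion_keys(e.phonemes):
            buckets[key].append(idx)

    seen: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a > b:
                    a, b = b, a
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                if is_neighbor(entries[a].phonemes, entries[b].phonemes):
                    g.add_edge(entries[a].word, entries[b].word)
    return g


def brute_force_edges(lexicon: Lexicon) -> set[frozenset[str]]:
    """All-pairs O(n²) edge set — the reference oracle for build_network."""
    entries = lexicon.entries
    edges: set[frozenset[str]] = set()
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            if is_neighbor(entries[i].phonemes, entries[j].phonemes):
                edges.add(frozenset((entries[i].word, entries[j].word)))
    return edges


@dataclass
class InflectionReport:
    """Edges removed by the inflection filter."""

    removed_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_edges)


def inflection_filter(
    network: nx.Graph,
    same_family: Callable[[dict, dict], bool] | None = None,
) -> tuple[nx.Graph, InflectionReport]:
    """Remove edges linking inflectional variants of the same lemma.

    By default two endpoints belong to the same family when their ``lemma``
    node attributes are equal (a node without a lemma annotation counts as
    its own lemma). A custom ``same_family`` predicate over the two nodes'
    attribute dicts can replace the default. No nodes are removed; the
    operation is idempotent.
    """
    if same_family is None:
        def same_family(a: dict, b: dict) -> bool:
            return a.get("lemma") == b.get("lemma") and a.get("lemma") is not None

    out = network.copy()
    report = InflectionReport()
    for u, v in network.edges:
        if same_family(network.nodes[u], network.nodes[v]):
            out.remove_edge(u, v)
            report.removed_edges.append((u, v))
    return out, report


def build_lemma_lexicon(lexicon: Lexicon) -> tuple[Lexicon, list[str]]:
    """Collapse a word-form lexicon to one entry per lemma.

    The lemma's transcription is taken from the word form whose orthography
    equals the lemma when present; otherwise from the family's
    highest-frequency form (ties by lexicographic word key). The lemma entry's
    frequency is the sum over the family. Returns the lemma lexicon and the
    list of lemmas whose own form was absent (transcription borrowed).
    """
    families: dict[str, list[LexicalEntry]] = defaultdict(list)
    for e in lexicon:
        families[e.lemma if e.lemma is not None else e.word].append(e)

    entries: list[LexicalEntry] = []
    borrowed: list[str] = []
    for lemma in families:
        fam = families[lemma]
        total = sum(e.frequency for e in fam)
        own = [e for e in fam if e.word == lemma]
        if own:
            source = own[0]
        else:
            source = sorted(fam, key=lambda e: (-e.frequency, e.word))[0]
            borrowed.append(lemma)
        entries.append(
            LexicalEntry(
                word=lemma,
                phonemes=source.phonemes,
                frequency=total,
                lemma=lemma,
                pos=source.pos,
            )
        )
    return Lexicon(entries), borrowed
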