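"""Lexicon and network I/O: TSV lexicons, IPA tokenization, ARPABET
conversion, and whitespace-separated adjacency-list serialization.

A lexicon is a table of word forms with phonemic transcriptions and corpus
frequencies. Transcriptions arrive as IPA strings and are segmented into
phoneme tokens against a :class:`PhonemeInventory` by greedy longest match,
so that multi-character symbols (affricates ``tʃ dʒ``, diphthongs
``aɪ aʊ ɔɪ eɪ oʊ``, rhotic vowels ``ɝ ɚ``) count as single phonemes —
the granularity of the CMU pronouncing dictionary that North American
English transcriptions typically derive from.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "LexicalEntry", "Lexicon", "PhonemeInventory", "default_inventory",
    "TokenizationError", "DuplicateWordError", "LoadReport",
    "tokenize_ipa", "arpabet_to_ipa", "read_cmu_dict",
    "read_lexicon", "write_lexicon", "read_adjlist", "write_adjlist",
]


class TokenizationError(ValueError):
    """A transcription contains material outside the phoneme inventory."""


class DuplicateWordError(ValueError):
    """Two lexicon rows share the same orthographic word key."""


@dataclass(frozen=True)
class LexicalEntry:
    """One word form: orthography (unique node key), phonemes, frequency."""

    word: str
    phonemes: tuple[str, ...]
    frequency: float = 0.0
    lemma: str | None = None
    pos: str | None = None

    def __post_init__(self) -> None:
        if not self.word:
            raise ValueError("word must be nonempty")
        if not self.phonemes:
            raise ValueError(f"entry {self.word!r}: phonemes must be nonempty")
        if self.frequency < 0:
            raise ValueError(f"entry {self.word!r}: frequency must be >= 0")

    @property
    def length(self) -> int:
        """Word length in phonemes."""
        return len(self.phonemes)


@dataclass
class Lexicon:
    """An ordered collection of lexical entries with unique word keys."""

    entries: list[LexicalEntry]

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            if e.word in seen:
                raise DuplicateWordError(
                    f"duplicate word key {e.word!r} (entries {seen[e.word]} and {i})"
                )
            seen[e.word] = i
        self._index = seen

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> LexicalEntry:
        return self.entries[self._index[word]]

    @property
    def inventory(self) -> set[str]:
        """Set of phoneme tokens observed across all entries."""
        inv: set[str] = set()
        for e in self.entries:
            inv.update(e.phonemes)
        return inv

    def words(self) -> list[str]:
        return [e.word for e in self.entries]


@dataclass(frozen=True)
class PhonemeInventory:
    """Segmentation inventory: recognized phoneme tokens plus ignorable marks.

    Tokens may be multi-character; segmentation is greedy longest match, so a
    token that is a prefix of another (``t`` vs ``tʃ``) is resolved in favor
    of the longer one. ``ignorable`` marks (stress, length) are stripped
    before matching and never intersect the token set.
    """

    tokens: frozenset[str]
    ignorable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.tokens & self.ignorable
        if overlap:
            raise ValueError(f"tokens and ignorable marks overlap: {sorted(overlap)}")

    @property
    def max_token_len(self) -> int:
        return max(len(t) for t in self.tokens)


# General-American default: 24 consonants, monophthongs, five diphthongs and
# two rhotic vowels as single tokens. Both 'g' (U+0067) and 'ɡ' (U+0261) are
# accepted since IPA sources vary.
_GA_CONSONANTS = (
    "p b t d k g ɡ tʃ dʒ f v θ ð s z ʃ ʒ h m n ŋ l ɹ r j w".split()
)
_GA_VOWELS = (
    "i ɪ e ɛ æ ɑ ɒ ɔ o ʊ u ʌ ə ɝ ɚ aɪ aʊ ɔɪ eɪ oʊ".split()
)
_IGNORABLE = ("ˈ", "ˌ", "ː", ".", "ˑ", "‿", " ")


def default_inventory() -> PhonemeInventory:
    """The default General-American IPA inventory."""
    return PhonemeInventory(
        tokens=frozenset(_GA_CONSONANTS) | frozenset(_GA_VOWELS),
        ignorable=frozenset(_IGNORABLE),
    )


def tokenize_ipa(transcription: str, inventory: PhonemeInventory | None = None) -> tuple[str, ...]:
    """Segment an IPA string into phoneme tokens by greedy longest match.

    Ignorable marks are stripped first. Raises :class:`TokenizationError`
    naming the offending character and its position if any character is not
    covered. The concatenation of the returned tokens equals the input with
    ignorable marks removed.
    """
    if inventory is None:
        inventory = default_inventory()
    if not transcription:
        raise TokenizationError("empty transcription")
    s = "".join(ch for ch in transcription if ch not in inventory.ignorable)
    if not s:
        raise TokenizationError(f"transcription {transcription!r} is all ignorable marks")
    out: list[str] = []
    i, n = 0, len(s)
    maxlen = inventory.max_token_len
    while i < n:
        for L in range(min(maxlen, n - i), 0, -1):
            cand = s[i : i + L]
            if cand in inventory.tokens:
                out.append(cand)
                i += L
                break
        else:
            raise TokenizationError(
                f"character {s[i]!r} at position {i} of {s!r} not in inventory"
            )
    return tuple(out)


# CMU ARPABET (39 symbols) -> IPA, diphthongs and rhotic vowels as one token.
ARPABET_TO_IPA: Mapping[str, str] = {
    "AA": "ɑ", "AE": "æ", "AH": "ʌ", "AO": "ɔ", "AW": "aʊ", "AY": "aɪ",
    "B": "b", "CH": "tʃ", "D": "d", "DH": "ð", "EH": "ɛ", "ER": "ɝ",
    "EY": "eɪ", "F": "f", "G": "g", "HH": "h", "IH": "ɪ", "IY": "i",
    "JH": "dʒ", "K": "k", "L": "l", "M": "m", "N": "n", "NG": "ŋ",
    "OW": "oʊ", "OY": "ɔɪ", "P": "p", "R": "ɹ", "S": "s", "SH": "ʃ",
    "T": "t", "TH": "θ", "UH": "ʊ", "UW": "u", "V": "v", "W": "w",
    "Y": "j", "Z": "z", "ZH": "ʒ",
}


def arpabet_to_ipa(pronunciation: Sequence[str]) -> tuple[str, ...]:
    """Map an ARPABET token sequence (optional 0/1/2 stress digits) to IPA.

    One ARPABET symbol maps to exactly one IPA token, so length is preserved.
    """
    out: list[str] = []
    for tok in pronunciation:
        base = tok.rstrip("012")
        try:
            out.append(ARPABET_TO_IPA[base.upper()])
        except KeyError:
            raise ValueError(f"unknown ARPABET symbol {tok!r}") from None
    return tuple(out)


def read_cmu_dict(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a CMU-dictionary flat file (``WORD  PH1 PH2 ...``) to IPA.

    Comment lines starting with ``;;;`` are skipped; alternate pronunciations
    marked ``WORD(1)`` are ignored (the primary entry wins).
    """
    out: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";;;"):
                continue
            parts = line.split()
            word = parts[0]
            if "(" in word:  # alternate pronunciation
                continue
            out[word.lower()] = arpabet_to_ipa(parts[1:])
    return out


@dataclass
class LoadReport:
    """Row accounting from :func:`read_lexicon`."""

    n_read: int = 0
    n_kept: int = 0
    skipped_rows: list[int] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_rows)


DEFAULT_COLUMNS = {
    "word": "Word",
    "ipa": "IPA",
    "frequency": "FREQcount",
    "lemma": "Lemma",
    "pos": "POS",
}


def read_lexicon(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    inventory: PhonemeInventory | None = None,
    delimiter: str = "\t",
) -> tuple[Lexicon, LoadReport]:
    """Read a delimited lexicon file into a tokenized :class:`Lexicon`.

    ``column_map`` maps the logical fields ``word``, ``ipa``, ``frequency``
    and optionally ``lemma``/``pos`` to header names in the file. Rows with
    an empty word or transcription are skipped and counted in the returned
    :class:`LoadReport`. Duplicate word keys raise
    :class:`DuplicateWordError` naming both rows.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    if inventory is None:
        inventory = default_inventory()

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    report = LoadReport()
    entries: list[LexicalEntry] = []
    first_row: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        fields = reader.fieldnames or []
        for logical in ("word", "ipa", "frequency"):
            if cmap[logical] not in fields:
                raise KeyError(
                    f"column {cmap[logical]!r} (for {logical!r}) not in header {fields}"
                )
        has_lemma = cmap.get("lemma") in fields
        has_pos = cmap.get("pos") in fields
        for rowno, row in enumerate(reader, start=2):  # header is line 1
            report.n_read += 1
            word = (row[cmap["word"]] or "").strip()
            ipa = (row[cmap["ipa"]] or "").strip()
            if not word or not ipa:
                report.skipped_rows.append(rowno)
                continue
            if word in first_row:
                raise DuplicateWordError(
                    f"duplicate word key {word!r} at rows {first_row[word]} and {rowno}"
                )
            first_row[word] = rowno
            freq = float(row[cmap["frequency"]] or 0.0)
            lemma = (row[cmap["lemma"]] or "").strip() or None if has_lemma else None
            pos = (row[cmap["pos"]] or "").strip() or None if has_pos else None
            entries.append(
                LexicalEntry(
                    word=word,
                    phonemes=tokenize_ipa(ipa, inventory),
                    frequency=freq,
                    lemma=lemma,
                    pos=pos,
                )
            )
            report.n_kept += 1
    return Lexicon(entries), report


def write_lexicon(lexicon: Lexicon, path: str | Path, delimiter: str = "\t") -> None:
    """Write a lexicon as a delimited file with the default column names."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["Word", "IPA", "FREQcount", "Lemma", "POS"])
        for e in lexicon:
            freq = int(e.frequency) if e.frequency == int(e.frequency) else e.frequency
            writer.writerow([e.word, "".join(e.phonemes), freq, e.lemma or "", e.pos or ""])


def write_adjlist(network: nx.Graph, path: str | Path) -> None:
    """Serialize an undirected graph as a whitespace-separated adjacency list.

    One line per node: the node key followed by its neighbors; each edge is
    written exactly once, on the line of its first-listed endpoint. Isolates
    get a line of their own so they survive round-tripping.
    """
    for node in network.nodes:
        s = str(node)
        if not s or s.split() != [s] or s.startswith("#"):
            raise ValueError(f"node key {node!r} contains whitespace or leading '#'")
    nx.write_adjlist(network, str(path))


def read_adjlist(path: str | Path) -> nx.Graph:
    """Read a whitespace-separated adjacency list into an undirected graph.

    Lines starting with ``#`` are comments. A neighbor equal to its own line's
    node (a self-loop) is rejected: similarity networks are simple graphs.
    """
    g = nx.read_adjlist(str(path))
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"self-loop(s) in adjacency list: {loops[:5]}")
    return g
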