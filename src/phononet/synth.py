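"""Seeded pseudo-lexicon generator.

Emulates the structure a phonological-network pipeline assumes of a real
transcribed lexicon, in the tradition of pseudo-lexicon studies where words
are built by drawing segments at random from a fixed sound inventory:

* phoneme strings drawn uniformly per position from a fixed inventory
  (19 consonants + 10 vowels by default), with an English-like word-length
  distribution over 2–8 phonemes peaked at 3–4 segments — short words are
  what give phonological networks their dense, clustered core;
* Zipfian token frequencies (rank-frequency slope −zipf_exponent), with
  frequency ranks biased toward shorter words (Zipf's law of abbreviation) —
  the correlation that makes smaller frequency-thresholded lexicons denser,
  as observed in real corpora;
* inflectional families: each base form spawns suffixed variants sharing
  its lemma annotation, so the inflection-edge filter has work to do.

What it deliberately does not emulate: phonotactics (segment order is
unconstrained), orthographic irregularity, and part-of-speech structure.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphs import brute_force_edges
from .lexicon import LexicalEntry, Lexicon
from .sampling import threshold_sample

import numpy as np

__all__ = ["SynthConfig", "generate", "generate_benchmark_suite", "tiny_lexicon"]

_DEFAULT_CONSONANTS = "p b t d k g m n ŋ f v s z ʃ h l ɹ w j".split()
_DEFAULT_VOWELS = "i ɪ ɛ æ ɑ ʌ ʊ u oʊ aɪ".split()

# English-like distribution of word length in phonemes (2-8), peaked at 3-4.
_DEFAULT_LENGTH_DIST = {2: 0.10, 3: 0.26, 4: 0.26, 5: 0.18, 6: 0.11, 7: 0.06, 8: 0.03}

# ASCII-safe spellings for word keys (adjacency lists are whitespace-separated)
_ORTHO = {"ŋ": "ng", "ʃ": "sh", "ɹ": "r", "ɪ": "i2", "ɛ": "e", "æ": "ae",
          "ɑ": "a", "ʌ": "u2", "ʊ": "u3", "oʊ": "ow", "aɪ": "ay"}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: inventory, lengths, frequencies, inflection."""

    n_lemmas: int = 1000
    consonants: tuple[str, ...] = tuple(_DEFAULT_CONSONANTS)
    vowels: tuple[str, ...] = tuple(_DEFAULT_VOWELS)
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_DIST)
    )
    zipf_exponent: float = 1.0
    # Gumbel-noise scale for the length-biased rank assignment; larger means
    # weaker length-frequency correlation (inf would decouple them entirely)
    length_rank_noise: float = 2.0
    inflection_rules: tuple[tuple[tuple[str, ...], float], ...] = (
        (("z",), 0.35),
        (("d",), 0.20),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lemmas < 1:
            raise ValueError("n_lemmas must be >= 1")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length probabilities sum to {total}, not 1")
        for _, p in self.inflection_rules:
            if not 0.0 <= p <= 1.0:
                raise ValueError("inflection probabilities must be in [0, 1]")

    @property
    def inventory(self) -> tuple[str, ...]:
        return self.consonants + self.vowels


def _spell(phonemes: tuple[str, ...]) -> str:
    return "".join(_ORTHO.get(p, p) for p in phonemes)


def generate(config: SynthConfig) -> Lexicon:
    """Generate a pseudo-lexicon per the config; deterministic given seed.

    Base forms are rejection-sampled for uniqueness; each inflection rule
    fires independently per base with its probability, appending its suffix.
    Frequencies follow a Zipf law over a seeded random rank permutation of
    all word forms.
    """
    rng = np.random.default_rng(config.seed)
    inv = list(config.inventory)
    lengths = sorted(config.length_distribution)
    probs = np.array([config.length_distribution[L] for L in lengths])

    n_strings = sum(len(inv) ** L for L in lengths)
    if config.n_lemmas > 0.5 * n_strings:
        raise ValueError(
            f"inventory too small: {config.n_lemmas} lemmas requested from "
            f"~{n_strings} possible strings"
        )

    bases: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(bases) < config.n_lemmas:
        attempts += 1
        if attempts > 50 * config.n_lemmas:
            raise ValueError("inventory too small to produce unique base forms")
        L = int(rng.choice(lengths, p=probs))
        form = tuple(inv[i] for i in rng.integers(len(inv), size=L))
        if form in seen:
            continue
        seen.add(form)
        bases.append(form)

    entries: list[LexicalEntry] = []
    used_words: set[str] = set()

    def unique_word(stem: str) -> str:
        word = stem
        k = 2
        while word in used_words:
            word = f"{stem}~{k}"
            k += 1
        used_words.add(word)
        return word

    for base in bases:
        lemma_word = unique_word(_spell(base))
        entries.append(LexicalEntry(word=lemma_word, phonemes=base, lemma=lemma_word))
        for suffix, p in config.inflection_rules:
            if rng.random() < p:
                inflected = base + tuple(suffix)
                entries.append(
                    LexicalEntry(
                        word=unique_word(_spell(inflected)),
                        phonemes=inflected,
                        lemma=lemma_word,
                    )
                )

    # Zipf frequencies; ranks biased toward shorter words (law of
    # abbreviation): rank by word length plus Gumbel noise
    scores = np.array([e.length for e in entries], dtype=float)
    scores += config.length_rank_noise * rng.gumbel(size=len(entries))
    ranks = np.empty(len(entries), dtype=int)
    ranks[np.argsort(scores, kind="stable")] = np.arange(1, len(entries) + 1)
    freqs = 1e6 * ranks.astype(float) ** (-config.zipf_exponent)
    entries = [
        LexicalEntry(word=e.word, phonemes=e.phonemes, frequency=float(f),
                     lemma=e.lemma, pos=e.pos)
        for e, f in zip(entries, freqs)
    ]
    return Lexicon(entries)


def tiny_lexicon() -> Lexicon:
    """A fixed ten-word lexicon with hand-checkable neighbor structure."""
    rows = [
        ("cat", ("k", "æ", "t"), 100.0, "cat"),
        ("cats", ("k", "æ", "t", "s"), 40.0, "cat"),
        ("cot", ("k", "ɑ", "t"), 30.0, "cot"),
        ("scat", ("s", "k", "æ", "t"), 5.0, "scat"),
        ("at", ("æ", "t"), 500.0, "at"),
        ("bat", ("b", "æ", "t"), 60.0, "bat"),
        ("bad", ("b", "æ", "d"), 70.0, "bad"),
        ("dog", ("d", "ɔ", "g"), 80.0, "dog"),
        ("dogs", ("d", "ɔ", "g", "z"), 25.0, "dog"),
        ("sprint", ("s", "p", "ɹ", "ɪ", "n", "t"), 8.0, "sprint"),
    ]
    return Lexicon(
        [LexicalEntry(word=w, phonemes=p, frequency=f, lemma=lem) for w, p, f, lem in rows]
    )


def generate_benchmark_suite(seed: int = 0) -> dict[str, dict]:
    """Named fixtures for download-free testing of every pipeline stage.

    ``tiny`` is a fixed 10-word lexicon whose edge manifest is computed by
    the brute-force pairwise oracle; ``small`` (1,000 words) and ``medium``
    (16,384 words) are generated then frequency-thresholded to exact sizes.
    Each fixture carries a manifest of expected invariant outcomes.
    """
    tiny = tiny_lexicon()
    suite = {
        "tiny": {
            "lexicon": tiny,
            "manifest": {
                "n": len(tiny),
                "edges": {tuple(sorted(e)) for e in brute_force_edges(tiny)},
            },
        }
    }
    small_full = generate(SynthConfig(n_lemmas=680, seed=seed))
    suite["small"] = {
        "lexicon": threshold_sample(small_full, 1000, seed=seed + 1),
        "manifest": {"n": 1000},
    }
    medium_full = generate(SynthConfig(n_lemmas=10_900, seed=seed + 2))
    suite["medium"] = {
        "lexicon": threshold_sample(medium_full, 16_384, seed=seed + 3),
        "manifest": {"n": 16_384, "gc_share_band": (0.30, 0.60)},
    }
    return suite
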