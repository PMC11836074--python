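"""Frequency-thresholded subsampling: size-controlled sub-lexicons.

Smaller lexicons are simulated by preferentially removing low-frequency
words, mimicking how a lexicon built from a smaller corpus would contain a
larger share of high-frequency words. Entries at or above the median
frequency are always retained when they fit; the remaining quota is filled
from below-median entries, either sampled without replacement with
probability proportional to frequency (``weighted``, the default) or by a
deterministic frequency cutoff (``top-n``).
"""

from __future__ import annotations

import warnings

import numpy as np

from .lexicon import Lexicon

__all__ = ["threshold_sample", "size_ladder"]


def _weighted_subset(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of a weighted sample without replacement of size k.

    Uses the exponential-race formulation: each item draws Exp(1)/w and the
    k smallest keys win, which is equivalent to successive
    probability-proportional-to-weight draws. Zero-weight items only enter
    once every positive-weight item is exhausted.
    """
    n = len(weights)
    if k >= n:
        return np.arange(n)
    keys = np.full(n, np.inf)
    pos = weights > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / weights[pos]
    n_pos = int(pos.sum())
    if k <= n_pos:
        return np.argsort(keys, kind="stable")[:k]
    # not enough positive-weight items: top up uniformly among zero-weight ones
    chosen = list(np.nonzero(pos)[0])
    zeros = np.nonzero(~pos)[0]
    extra = rng.choice(zeros, size=k - n_pos, replace=False)
    return np.concatenate([chosen, extra]).astype(int)


def threshold_sample(
    lexicon: Lexicon,
    target_size: int,
    seed: int,
    mode: str = "weighted",
) -> Lexicon:
    """Sample ``target_size`` entries, preferentially keeping frequent words.

    The median is computed on the input lexicon's frequency column; ties at
    the median count as above-median. All above-median entries are retained
    when they fit within ``target_size``; otherwise the sample is truncated
    by descending frequency (ties shuffled by the seed) with a warning. The
    below-median quota is filled by frequency-proportional sampling without
    replacement (``weighted``) or a pure frequency cutoff (``top-n``).
    Deterministic given the seed; input entry order is preserved.
    """
    n = len(lexicon)
    if not 1 <= target_size <= n:
        raise ValueError(f"target_size {target_size} outside [1, {n}]")
    if target_size == n:
        return Lexicon(list(lexicon.entries))
    rng = np.random.default_rng(seed)
    freqs = np.array([e.frequency for e in lexicon], dtype=float)
    median = float(np.median(freqs))
    above = np.nonzero(freqs >= median)[0]
    below = np.nonzero(freqs < median)[0]

    if target_size < len(above):
        warnings.warn(
            f"target_size {target_size} below above-median count {len(above)}; "
            "truncating by descending frequency",
            stacklevel=2,
        )
        jitter = rng.permutation(len(above))
        order = sorted(range(len(above)), key=lambda i: (-freqs[above[i]], jitter[i]))
        keep = set(above[i] for i in order[:target_size])
    else:
        quota = target_size - len(above)
        if mode == "weighted":
            picked = below[_weighted_subset(rng, freqs[below], quota)]
        elif mode == "top-n":
            jitter = rng.permutation(len(below))
            order = sorted(range(len(below)), key=lambda i: (-freqs[below[i]], jitter[i]))
            picked = below[[order[i] for i in range(quota)]]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        keep = set(above) | set(int(i) for i in picked)

    return Lexicon([e for i, e in enumerate(lexicon.entries) if i in keep])


def size_ladder(
    lexicon: Lexicon,
    sizes: list[int],
    seed: int,
    mode: str = "weighted",
) -> list[Lexicon]:
    """Nested ladder of sub-lexicons at the given ascending sizes.

    Built top-down: the largest sample is drawn from the full lexicon and
    each smaller sample from the next larger one, so every smaller lexicon
    is a subset of every larger one and the resulting networks are directly
    comparable.
    """
    if sizes != sorted(sizes):
        raise ValueError("sizes must be sorted ascending")
    if sizes and sizes[-1] > len(lexicon):
        raise ValueError(f"largest size {sizes[-1]} exceeds lexicon size {len(lexicon)}")
    ladder: list[Lexicon] = []
    current = lexicon
    for level, size in enumerate(reversed(sizes)):
        current = threshold_sample(current, size, seed=seed + level, mode=mode)
        ladder.append(current)
    ladder.reverse()
    return ladder
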