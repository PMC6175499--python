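"""SAX words, 90-degree-shift search patterns, and phase-shifted pair search.

Two genes whose pulses rise and fall a quarter period apart trace a loop when
plotted against each other.  To find such pairs each gene's composite time
course is z-normalized and discretised into a SAX word (one symbol per time
point by default, symbols being the equiprobable regions of the standard
normal).  Shifting a word right by ``floor(T/4)`` symbols — padding the front
with wildcards — yields its search pattern; any other gene whose word matches
the pattern (Hamming distance over the non-wildcard positions at or below a
threshold, 0 by default) lags the first gene by a quarter period, and the
ordered pair is emitted as a loop candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

WILDCARD = "?"
_SYMBOLS = "abcdefghijklmnopqrst"

MAX_ALPHABET = len(_SYMBOLS)


@dataclass
class SaxConfig:
    """Settings for SAX discretisation and pattern search.

    ``word_length`` defaults to the series length (no piecewise aggregation;
    appropriate for short longitudinal grids).  ``shift_symbols`` defaults to
    ``floor(word_length / 4)``, the quarter-period shift.
    """

    alphabet_size: int = 4
    word_length: int | None = None
    shift_symbols: int | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.alphabet_size <= MAX_ALPHABET:
            raise ValueError(f"alphabet_size must be in [2, {MAX_ALPHABET}]")
        if self.word_length is not None and self.word_length < 1:
            raise ValueError("word_length must be positive")
        if self.shift_symbols is not None and self.shift_symbols < 1:
            raise ValueError("shift_symbols must be >= 1")

    def resolved_word_length(self, series_length: int) -> int:
        return self.word_length if self.word_length is not None else series_length

    def resolved_shift(self, word_length: int) -> int:
        shift = (
            self.shift_symbols
            if self.shift_symbols is not None
            else word_length // 4
        )
        if shift < 1:
            raise ValueError(
                f"quarter-period shift of a {word_length}-symbol word rounds "
                "to 0; provide shift_symbols explicitly"
            )
        if shift >= word_length:
            raise ValueError(
                f"shift_symbols ({shift}) must be smaller than the word "
                f"length ({word_length})"
            )
        return shift


@dataclass
class SaxWord:
    """A gene's SAX word plus (optionally) its shifted search pattern."""

    gene: str
    word: str
    search_pattern: str = ""

    def __post_init__(self) -> None:
        bad = set(self.word) - set(_SYMBOLS)
        if bad:
            raise ValueError(f"word contains non-alphabet symbols: {sorted(bad)}")


@dataclass(order=True)
class LoopCandidate:
    """An ordered candidate pair: ``lead_gene`` peaks first, ``lag_gene`` follows."""

    match_distance: int
    lead_gene: str
    lag_gene: str

    def __post_init__(self) -> None:
        if self.lead_gene == self.lag_gene:
            raise ValueError("lead and lag gene must differ")
        if self.match_distance < 0:
            raise ValueError("match_distance must be >= 0")


def znormalize(series: Sequence[float]) -> np.ndarray:
    """Standardise a series to mean 0 and population standard deviation 1."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("series must be 1-D with at least 2 values")
    sd = arr.std()
    if sd <= 1e-12:
        raise ValueError("zero variance: constant series cannot be symbolized")
    return (arr - arr.mean()) / sd


def sax_breakpoints(alphabet_size: int) -> np.ndarray:
    """Interior breakpoints splitting N(0,1) into equiprobable regions."""
    return norm.ppf(np.arange(1, alphabet_size) / alphabet_size)


def _paa(z: np.ndarray, word_length: int) -> np.ndarray:
    if z.size % word_length:
        raise ValueError(
            f"series length {z.size} is not divisible by word_length "
            f"{word_length}; piecewise aggregation needs equal blocks"
        )
    return z.reshape(word_length, -1).mean(axis=1)


def to_sax(series: Sequence[float], cfg: SaxConfig | None = None, gene: str = "") -> SaxWord:
    """Convert a time series into a SAX word.

    Values are z-normalized, optionally aggregated into ``word_length``
    equal-length segments, then each value is mapped to the symbol of the
    standard-normal region ``[b_{i-1}, b_i)`` it falls in (lower-inclusive).
    """
    cfg = cfg or SaxConfig()
    z = znormalize(series)
    wl = cfg.resolved_word_length(z.size)
    if wl < z.size:
        z = _paa(z, wl)
    elif wl > z.size:
        raise ValueError("word_length cannot exceed the series length")
    bp = sax_breakpoints(cfg.alphabet_size)
    idx = np.searchsorted(bp, z, side="right")
    return SaxWord(gene=gene, word="".join(_SYMBOLS[i] for i in idx))


def make_search_pattern(word: SaxWord, cfg: SaxConfig | None = None) -> SaxWord:
    """Fill in a word's quarter-period search pattern.

    The pattern is the word shifted right by ``shift_symbols`` positions:
    leading wildcards, trailing symbols discarded (the time course is not
    periodic, so no wrap-around).
    """
    cfg = cfg or SaxConfig()
    shift = cfg.resolved_shift(len(word.word))
    pattern = WILDCARD * shift + word.word[: len(word.word) - shift]
    return replace(word, search_pattern=pattern)


def pattern_distance(candidate_word: str, pattern: str) -> int:
    """Hamming distance over the pattern's non-wildcard positions."""
    if len(candidate_word) != len(pattern):
        raise ValueError(
            f"word length {len(candidate_word)} != pattern length {len(pattern)}"
        )
    return sum(
        1 for w, p in zip(candidate_word, pattern) if p != WILDCARD and w != p
    )


def find_phase_shifted_pairs(
    words: Sequence[SaxWord],
    cfg: SaxConfig | None = None,
    max_distance: int = 0,
) -> list[LoopCandidate]:
    """Enumerate ordered gene pairs whose lag word matches the lead's pattern.

    For every ordered pair ``(lead, lag)`` of distinct genes, a
    :class:`LoopCandidate` is emitted when the Hamming distance between the
    lag gene's word and the lead gene's search pattern is at most
    ``max_distance``.  The list is sorted by (distance, lead, lag).
    """
    if len(words) < 2:
        raise ValueError("need at least two words to search for pairs")
    cfg = cfg or SaxConfig()
    prepared = [
        w if w.search_pattern else make_search_pattern(w, cfg) for w in words
    ]
    candidates: list[LoopCandidate] = []
    for lead in prepared:
        for lag in prepared:
            if lead.gene == lag.gene:
                continue
            d = pattern_distance(lag.word, lead.search_pattern)
            if d <= max_distance:
                candidates.append(
                    LoopCandidate(
                        match_distance=d, lead_gene=lead.gene, lag_gene=lag.gene
                    )
                )
    candidates.sort()
    return candidates


def possible_pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs among ``n_genes`` genes."""
    return n_genes * (n_genes - 1) // 2
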