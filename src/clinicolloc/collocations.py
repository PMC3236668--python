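"""Bigram/trigram tables and pointwise-mutual-information ranking.

Collocations are contiguous token pairs or triples that co-occur more often
than expected were the tokens independent. For a bigram with window count
c12 over W windows and unigram counts c1, c2 over T tokens,

    PMI = log2( (c12 / W) / ((c1 / T) * (c2 / T)) )

and the trigram form uses the product of the three unigram probabilities.
Candidates are ranked by PMI within each n-gram order and the top k of each
order are selected for human classification.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .tokens import FreqTable, TokenStream

logger = logging.getLogger(__name__)

DEFAULT_K_PER_TYPE = 300
DEFAULT_MIN_COUNT = 2


@dataclass
class NGramTable:
    """Counts of contiguous n-token windows (n = 2 or 3)."""

    n: int
    counts: Counter = field(default_factory=Counter)
    window_total: int = 0

    @property
    def distinct(self) -> int:
        """Number of distinct n-gram types (the headline n-gram count)."""
        return len(self.counts)

    def __getitem__(self, words: tuple) -> int:
        return self.counts[tuple(words)]

    def __contains__(self, words: tuple) -> bool:
        return tuple(words) in self.counts


@dataclass(frozen=True)
class ScoredCollocation:
    words: tuple[str, ...]
    count: int
    pmi: float


def build_ngrams(
    streams: Iterable[TokenStream], n: int, span_messages: bool = False
) -> NGramTable:
    """Count contiguous n-grams over content streams.

    With ``span_messages=False`` windows never cross a message boundary;
    with ``True`` the streams are concatenated (in corpus order) into one
    merged stream first, reproducing counting over a single merged file.
    """
    if n not in (2, 3):
        raise ValueError(f"n must be 2 or 3, got {n}")
    counts: Counter = Counter()
    window_total = 0
    if span_messages:
        sequences: list[Sequence[str]] = [
            [w for s in streams for w in s.words]
        ]
    else:
        sequences = [s.words for s in streams]
    for words in sequences:
        m = len(words) - n + 1
        if m <= 0:
            continue
        window_total += m
        for i in range(m):
            counts[tuple(words[i : i + n])] += 1
    return NGramTable(n=n, counts=counts, window_total=window_total)


def pmi(words: Sequence[str], ngram_table: NGramTable, unigram_freq: FreqTable) -> float:
    """Pointwise mutual information of an n-gram, in bits."""
    words = tuple(words)
    c_ngram = ngram_table[words]
    if c_ngram == 0:
        raise ValueError(f"n-gram {words!r} not present in table")
    W = ngram_table.window_total
    T = unigram_freq.token_total
    p_ngram = c_ngram / W
    p_indep = 1.0
    for w in words:
        c = unigram_freq[w]
        if c == 0:
            raise ValueError(f"unigram {w!r} not present in frequency table")
        p_indep *= c / T
    return math.log2(p_ngram / p_indep)


def top_collocations(
    tables: Sequence[NGramTable],
    unigram_freq: FreqTable,
    k_per_type: int = DEFAULT_K_PER_TYPE,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[ScoredCollocation]:
    """Top-k PMI-ranked collocations per n-gram order (bigrams then trigrams).

    Candidates below ``min_count`` are excluded (PMI at count 1 maximally
    rewards noise). Ties sort by count descending, then lexicographically.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out: list[ScoredCollocation] = []
    for table in sorted(tables, key=lambda t: t.n):
        scored = [
            ScoredCollocation(words=words, count=c, pmi=pmi(words, table, unigram_freq))
            for words, c in table.counts.items()
            if c >= min_count
        ]
        scored.sort(key=lambda sc: (-sc.pmi, -sc.count, sc.words))
        if len(scored) < k_per_type:
            logger.info(
                "only %d candidate %d-grams available (k=%d); returning all",
                len(scored), table.n, k_per_type,
            )
        out.extend(scored[:k_per_type])
    return out


def write_collocations_tsv(collocations: Iterable[ScoredCollocation], path) -> None:
    """Tab-separated output: rank, n, words (space-joined), count, pmi_bits."""
    from pathlib import Path

    lines = ["rank\tn\twords\tcount\tpmi_bits"]
    for rank, sc in enumerate(collocations, start=1):
        lines.append(f"{rank}\t{len(sc.words)}\t{' '.join(sc.words)}\t{sc.count}\t{sc.pmi:.4f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_collocations_tsv(path) -> list[ScoredCollocation]:
    from pathlib import Path

    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines()[1:]:
        if not line.strip():
            continue
        _, _, words, count, pmi_bits = line.split("\t")
        out.append(
            ScoredCollocation(words=tuple(words.split()), count=int(count), pmi=float(pmi_bits))
        )
    return out
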