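"""Tokenisation and the two-stage content filter.

Stage 1 mirrors the initial pass over the merged, date-sorted corpus:
lowercased maximal runs of letter characters, keeping only tokens longer
than 3 characters, with stopwords removed. Stage 2 keeps the clinically
content-bearing tokens: length greater than 5 and corpus-wide frequency
greater than 7. The surviving type set is the community's working
vocabulary and the input to collocation discovery.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

# maximal runs of Unicode letters; digits/underscores/hyphens split tokens
LETTER_RUN = re.compile(r"[^\W\d_]+")

MIN_TOKEN_LEN = 4  # stage 1: "length >3"
CONTENT_MIN_LEN = 6  # stage 2: "length >5"
CONTENT_MIN_FREQ = 8  # stage 2: "frequency >7"


@dataclass
class TokenStream:
    """Ordered (token, character offset) pairs for one message."""

    message_id: int
    tokens: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.tokens)

    @property
    def words(self) -> list[str]:
        return [t for t, _ in self.tokens]


@dataclass
class FreqTable:
    """Corpus-wide token type counts."""

    counts: Counter = field(default_factory=Counter)

    def __getitem__(self, token: str) -> int:
        return self.counts[token]

    def __contains__(self, token: str) -> bool:
        return token in self.counts

    def items(self):
        return self.counts.items()

    @property
    def token_total(self) -> int:
        return sum(self.counts.values())

    @property
    def type_count(self) -> int:
        return len(self.counts)

    def most_common(self, n: Optional[int] = None):
        return self.counts.most_common(n)


def load_stopwords(path: Optional[str | Path] = None) -> frozenset[str]:
    """Load a stopword list (one lowercase word per line).

    With no path, returns the packaged 127-word English list.
    """
    if path is None:
        text = resources.files("clinicolloc.data").joinpath("stopwords_en.txt").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def tokenize(text: str, message_id: int = 0, min_len: int = MIN_TOKEN_LEN) -> TokenStream:
    """Lowercased letter-run tokens of length >= ``min_len`` with offsets."""
    tokens = [
        (m.group(0).lower(), m.start())
        for m in LETTER_RUN.finditer(text)
        if len(m.group(0)) >= min_len
    ]
    return TokenStream(message_id=message_id, tokens=tokens)


def remove_stopwords(stream: TokenStream, stoplist: frozenset[str] | set[str]) -> TokenStream:
    """Drop stoplisted tokens; surviving offsets are unchanged."""
    return TokenStream(
        message_id=stream.message_id,
        tokens=[(t, o) for t, o in stream.tokens if t not in stoplist],
    )


def build_freq_table(streams: Iterable[TokenStream]) -> FreqTable:
    counts: Counter = Counter()
    for s in streams:
        counts.update(s.words)
    return FreqTable(counts=counts)


def content_filter(
    streams: Iterable[TokenStream],
    freq: FreqTable,
    min_len: int = CONTENT_MIN_LEN,
    min_freq: int = CONTENT_MIN_FREQ,
) -> tuple[list[TokenStream], FreqTable]:
    """Keep tokens with length >= ``min_len`` and corpus frequency >= ``min_freq``.

    ``freq`` must be the table built over the input streams; a fresh table
    over the survivors is returned alongside the filtered streams.
    """
    out_streams = []
    for s in streams:
        kept = [
            (t, o) for t, o in s.tokens if len(t) >= min_len and freq[t] >= min_freq
        ]
        out_streams.append(TokenStream(message_id=s.message_id, tokens=kept))
    return out_streams, build_freq_table(out_streams)


def tokenize_corpus(
    clean_messages: Iterable,
    stoplist: Optional[frozenset[str]] = None,
    min_len: int = MIN_TOKEN_LEN,
) -> list[TokenStream]:
    """Stage-1 token streams (length filter + stopword removal) per message."""
    if stoplist is None:
        stoplist = load_stopwords()
    return [
        remove_stopwords(tokenize(m.text, message_id=m.id, min_len=min_len), stoplist)
        for m in clean_messages
    ]
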