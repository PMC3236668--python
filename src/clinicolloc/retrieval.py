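"""Proximity retrieval: compile phrase/keyword queries, match, sort, report.

Discovered phrases are turned into order-free proximity queries: a message
matches when every word of the phrase occurs (whole-word, case-insensitive)
with at most ``max_gap`` characters between consecutive matched words in
text order — words were often reordered in the raw messages, so order is
ignored. Keywords match as single whole words; keywords adjacent in a
phrase additionally yield an ordered concatenated search string. Matching
runs on cleaned message text (not the NLP-filtered token stream). Matched
messages are deduplicated into per-category folders by kind of match, plus
aggregate folders, and summarised in a per-category count table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .corpus_io import write_message_file
from .lexicon import Lexicon

DEFAULT_MAX_GAP = 100

_NONLETTER = r"[\W\d_]"


def _whole_word(word: str) -> re.Pattern:
    return re.compile(rf"(?<![^\W\d_]){re.escape(word)}(?![^\W\d_])", re.IGNORECASE)


def _term_pattern(term: str) -> re.Pattern:
    """Whole-word pattern for a term of one or more space-separated words;
    multiword terms match in order separated by any non-letter run."""
    words = term.split()
    body = rf"{_NONLETTER}+".join(re.escape(w) for w in words)
    return re.compile(rf"(?<![^\W\d_]){body}(?![^\W\d_])", re.IGNORECASE)


@dataclass(frozen=True)
class PhraseQuery:
    words: frozenset[str]
    max_gap: int = DEFAULT_MAX_GAP
    order_free: bool = True
    source: tuple[str, ...] = ()

    def __post_init__(self):
        if not (2 <= len(self.words) <= 3):
            raise ValueError(f"phrase query needs 2-3 distinct words, got {sorted(self.words)}")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class KeywordQuery:
    term: str  # single word, or space-separated ordered concatenation

    def __post_init__(self):
        if not self.term.strip():
            raise ValueError("keyword query term must be nonempty")


@dataclass
class Match:
    message_id: int
    category: str
    kind: str  # "phrase" | "keyword"
    query: Union[tuple[str, ...], str]
    spans: list[tuple[int, int]]
    gaps: list[int] = field(default_factory=list)
    stripped_gaps: list[int] = field(default_factory=list)


def compile_phrase_query(
    phrase: Sequence[str], max_gap: int = DEFAULT_MAX_GAP
) -> PhraseQuery:
    """Order-free proximity query over a 2-3 word phrase."""
    phrase = tuple(w.lower() for w in phrase)
    if not (2 <= len(phrase) <= 3):
        raise ValueError(f"phrase must have 2 or 3 words, got {len(phrase)}")
    return PhraseQuery(words=frozenset(phrase), max_gap=max_gap, source=phrase)


def build_keyword_queries(
    keywords: Iterable[str], phrases: Iterable[Sequence[str]] = ()
) -> list[KeywordQuery]:
    """Each keyword as a query, plus ordered concatenations of keywords that
    appear adjacent within a phrase."""
    kws = [k.lower() for k in dict.fromkeys(keywords)]
    kwset = set(kws)
    terms = list(kws)
    seen = set(kws)
    for phrase in phrases:
        words = [w.lower() for w in phrase]
        # maximal runs of adjacent keywords, order preserved
        i = 0
        while i < len(words):
            if words[i] in kwset:
                j = i
                while j + 1 < len(words) and words[j + 1] in kwset:
                    j += 1
                if j > i:
                    term = " ".join(words[i : j + 1])
                    if term not in seen:
                        seen.add(term)
                        terms.append(term)
                i = j + 1
            else:
                i += 1
    return [KeywordQuery(term=t) for t in terms]


def _stripped_len(segment: str) -> int:
    """Characters in the segment excluding whitespace and punctuation."""
    return sum(1 for c in segment if c.isalnum())


def _find_occurrences(text: str, words: Iterable[str]) -> list[tuple[int, int, str]]:
    occ = []
    for w in set(words):
        for m in _whole_word(w).finditer(text):
            occ.append((m.start(), m.end(), w.lower()))
    occ.sort()
    return occ


def _best_window(occ, start_idx, needed, max_gap, text):
    """Smallest-end valid chain starting at occ[start_idx] covering ``needed``.

    Chains pick one occurrence per remaining word, forward in text order,
    with each consecutive inclusive gap <= max_gap. Exhaustive search with
    gap pruning (word sets have at most 3 members, so at most two levels).
    """
    start = occ[start_idx]
    best: Optional[list] = None

    def extend(chain, remaining):
        nonlocal best
        if not remaining:
            if best is None or chain[-1][1] < best[-1][1]:
                best = list(chain)
            return
        last_end = chain[-1][1]
        for cand in occ:
            if cand[0] < last_end:
                continue
            gap = cand[0] - last_end
            if gap > max_gap:
                break  # occ sorted by start: later candidates only widen the gap
            if cand[2] in remaining:
                chain.append(cand)
                extend(chain, remaining - {cand[2]})
                chain.pop()

    extend([start], needed - {start[2]})
    return best


def match_message(clean, query: Union[PhraseQuery, KeywordQuery]) -> list[Match]:
    """Whole-word, case-insensitive matches of one query against one message.

    Phrase instances are leftmost non-overlapping windows; each instance
    consumes its matched word occurrences. Gap bookkeeping records both the
    inclusive character gap (drives matching) and a secondary count
    excluding whitespace and punctuation.
    """
    text = clean.text
    if isinstance(query, KeywordQuery):
        pat = _term_pattern(query.term)
        return [
            Match(
                message_id=clean.id,
                category="",
                kind="keyword",
                query=query.term,
                spans=[(m.start(), m.end())],
            )
            for m in pat.finditer(text)
        ]

    occ = _find_occurrences(text, query.words)
    matches: list[Match] = []
    i = 0
    while i < len(occ):
        window = _best_window(occ, i, set(query.words), query.max_gap, text)
        if window is None:
            i += 1
            continue
        spans = [(s, e) for s, e, _ in window]
        gaps = [window[k + 1][0] - window[k][1] for k in range(len(window) - 1)]
        stripped = [
            _stripped_len(text[window[k][1] : window[k + 1][0]])
            for k in range(len(window) - 1)
        ]
        matches.append(
            Match(
                message_id=clean.id,
                category="",
                kind="phrase",
                query=query.source or tuple(sorted(query.words)),
                spans=spans,
                gaps=gaps,
                stripped_gaps=stripped,
            )
        )
        window_end = window[-1][1]
        while i < len(occ) and occ[i][0] < window_end:
            i += 1
    return matches


@dataclass
class RetrievalSet:
    """Deduplicated per-(category x kind) message folders with match details."""

    matches: list[Match] = field(default_factory=list)
    folders: dict[tuple[str, str], set[int]] = field(default_factory=dict)
    instance_counts: Counter = field(default_factory=Counter)
    categories: list[str] = field(default_factory=list)

    def folder(self, category: str, kind: str) -> set[int]:
        return self.folders.get((category, kind), set())

    def aggregate(self, kind: str) -> set[int]:
        """Union over categories; kind in {"phrase", "keyword", "either"}."""
        out: set[int] = set()
        for (cat, k), ids in self.folders.items():
            if kind == "either" or k == kind:
                out |= ids
        return out

    def either_folder(self, category: str) -> set[int]:
        return self.folder(category, "phrase") | self.folder(category, "keyword")


def retrieve(
    clean_messages: Iterable,
    lexicon: Lexicon,
    categories: Optional[Sequence[str]] = None,
    max_gap: int = DEFAULT_MAX_GAP,
) -> RetrievalSet:
    """Run every selected category's phrase and keyword queries over the corpus."""
    if categories is None:
        categories = list(lexicon.categories)
    categories = [c.lower() for c in categories]
    for c in categories:
        if c not in lexicon:
            raise KeyError(f"unknown lexicon category {c!r}")

    queries: list[tuple[str, str, object]] = []
    for c in categories:
        cat = lexicon[c]
        for phrase in cat.phrases:
            queries.append((c, "phrase", compile_phrase_query(phrase, max_gap=max_gap)))
        for kq in build_keyword_queries(cat.keywords, cat.phrases):
            queries.append((c, "keyword", kq))

    rs = RetrievalSet(categories=categories)
    messages = list(clean_messages)
    for cat_name, kind, query in queries:
        for msg in messages:
            found = match_message(msg, query)
            for m in found:
                m.category = cat_name
            if found:
                rs.matches.extend(found)
                rs.folders.setdefault((cat_name, kind), set()).add(msg.id)
                rs.instance_counts[(cat_name, kind)] += len(found)
    return rs


def retrieval_report(rs: RetrievalSet):
    """Per-category message (instance) counts by kind of match, with a totals
    row where instance totals are sums and message totals are deduplicated
    unions across categories."""
    import pandas as pd

    rows = []
    for c in rs.categories:
        p_ids = rs.folder(c, "phrase")
        k_ids = rs.folder(c, "keyword")
        rows.append(
            {
                "category": c,
                "phrase_messages": len(p_ids),
                "phrase_instances": rs.instance_counts[(c, "phrase")],
                "keyword_messages": len(k_ids),
                "keyword_instances": rs.instance_counts[(c, "keyword")],
                "either_messages": len(p_ids | k_ids),
                "either_instances": rs.instance_counts[(c, "phrase")]
                + rs.instance_counts[(c, "keyword")],
            }
        )
    rows.append(
        {
            "category": "Total",
            "phrase_messages": len(rs.aggregate("phrase")),
            "phrase_instances": sum(r["phrase_instances"] for r in rows),
            "keyword_messages": len(rs.aggregate("keyword")),
            "keyword_instances": sum(r["keyword_instances"] for r in rows),
            "either_messages": len(rs.aggregate("either")),
            "either_instances": sum(r["either_instances"] for r in rows),
        }
    )
    return pd.DataFrame(rows)


def deliver(rs: RetrievalSet, clean_by_id: dict, outdir: str | Path) -> dict[str, int]:
    """Write deduplicated messages into ``out/<category>/<kind>/`` folders plus
    ``_all_phrase``, ``_all_keyword`` and ``_all_either`` aggregates.

    Returns a mapping folder path -> file count.
    """
    outdir = Path(outdir)
    written: dict[str, int] = {}

    def write_folder(rel: str, ids: set[int]) -> None:
        folder = outdir / rel
        folder.mkdir(parents=True, exist_ok=True)
        for mid in sorted(ids):
            write_message_file(clean_by_id[mid], folder)
        written[rel] = len(ids)

    for c in rs.categories:
        for kind in ("phrase", "keyword"):
            write_folder(f"{c.replace(' ', '_')}/{kind}", rs.folder(c, kind))
    write_folder("_all_phrase", rs.aggregate("phrase"))
    write_folder("_all_keyword", rs.aggregate("keyword"))
    write_folder("_all_either", rs.aggregate("either"))
    return written
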