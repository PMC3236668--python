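"""Workflow orchestration and descriptive reporting.

Runs the full chain — ingest, clean, tokenize, content-filter, collocate,
keyword extraction, retrieve, deliver — with stage-by-stage token/message
accounting, and computes the descriptive statistics of interest: stage
percentages (half-up rounding to the printed number of decimals) and the
cumulative author-participation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

from . import collocations as colloc_mod
from . import corpus_io, preprocess, retrieval, tokens
from .lexicon import EquivalenceMap, Lexicon, extract_keywords, load_lexicon

logger = logging.getLogger(__name__)


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding matches the convention of printed
    percentage tables.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent() denominator is zero")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return float(value)


def participation_distribution(
    corpus_or_counts,
    boundaries: Sequence[float] = (0.05, 0.11, 1.0),
    total_subscribers: Optional[int] = None,
):
    """Cumulative message share at each requested author-share boundary.

    Authors are ranked by message count descending (ties by author label).
    Boundaries are fractions of the subscriber list when
    ``total_subscribers`` is given (non-posting subscribers count toward the
    denominator), else fractions of the posting authors. Returns a DataFrame
    with one row per boundary; ``df.attrs`` carries posting/passive tallies.
    """
    import pandas as pd

    if hasattr(corpus_or_counts, "author_counts"):
        counts_map = corpus_or_counts.author_counts()
    else:
        counts_map = dict(corpus_or_counts)
    if not counts_map:
        raise ValueError("empty corpus: no author participation to report")
    ranked = sorted(counts_map.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = [c for _, c in ranked]
    total_messages = sum(counts)
    n_authors = len(counts)
    base = total_subscribers if total_subscribers else n_authors

    rows = []
    cum = 0
    prev_k = 0
    for b in boundaries:
        k = min(n_authors, max(1, round(b * base)))
        if k > prev_k:
            cum += sum(counts[prev_k:k])
            prev_k = k
        rows.append(
            {
                "author_share": b,
                "n_authors": k,
                "cum_messages": cum,
                "cum_message_share": cum / total_messages,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_posting"] = n_authors
    df.attrs["total_messages"] = total_messages
    if total_subscribers:
        df.attrs["n_passive"] = total_subscribers - n_authors
        df.attrs["posting_pct"] = percent(n_authors, total_subscribers, 1)
    return df


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    pct_of_reference: Optional[float] = None


@dataclass
class PipelineConfig:
    mailbox: str
    format: str = "mbox"
    patterns: Optional[str] = None
    names: Optional[str] = None
    places: Optional[str] = None
    stopwords: Optional[str] = None
    min_len: int = tokens.MIN_TOKEN_LEN
    content_min_len: int = tokens.CONTENT_MIN_LEN
    content_min_freq: int = tokens.CONTENT_MIN_FREQ
    k_per_type: int = colloc_mod.DEFAULT_K_PER_TYPE
    min_count: int = colloc_mod.DEFAULT_MIN_COUNT
    span_messages: bool = False
    lexicon: Optional[str] = None
    categories: Optional[list[str]] = None
    max_gap: int = retrieval.DEFAULT_MAX_GAP
    equiv: Optional[str] = None
    outdir: Optional[str] = None
    total_subscribers: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    corpus: corpus_io.Corpus
    clean: list
    streams_stage1: list
    freq_stage1: tokens.FreqTable
    streams_content: list
    freq_content: tokens.FreqTable
    bigrams: colloc_mod.NGramTable
    trigrams: colloc_mod.NGramTable
    collocations: list
    keywords: set
    retrieval_set: Optional[retrieval.RetrievalSet]
    report_table: Optional[object]
    stage_reports: list[StageReport] = field(default_factory=list)
    delivered: Optional[dict] = None
    participation: Optional[object] = None


def _load_wordlist(path: Optional[str]) -> tuple[str, ...]:
    if not path:
        return ()
    return tuple(
        w.strip().lower()
        for w in Path(path).read_text(encoding="utf-8").splitlines()
        if w.strip() and not w.startswith("#")
    )


def run_pipeline(
    config: PipelineConfig,
    corpus: Optional[corpus_io.Corpus] = None,
    lexicon: Optional[Lexicon] = None,
) -> PipelineResult:
    """Execute the full workflow; ``corpus``/``lexicon`` may be passed
    directly (e.g. from the synthetic generator) instead of being read from
    the configured paths."""
    reports: list[StageReport] = []

    if corpus is None:
        corpus = corpus_io.read_mailbox(config.mailbox, config.format)
    reports.append(StageReport("ingest", len(corpus) + corpus.n_skipped, len(corpus)))
    logger.info("ingest: %d messages", len(corpus))

    rules = (
        preprocess.NoiseRuleSet.from_file(config.patterns)
        if config.patterns
        else preprocess.NoiseRuleSet.default()
    )
    names = _load_wordlist(config.names)
    places = _load_wordlist(config.places)
    clean = preprocess.clean_corpus(corpus, rules, names, places)
    reports.append(StageReport("clean", len(corpus), len(clean)))

    raw_token_total = sum(len(tokens.LETTER_RUN.findall(m.text)) for m in clean)
    stoplist = tokens.load_stopwords(config.stopwords)
    streams1 = tokens.tokenize_corpus(clean, stoplist, min_len=config.min_len)
    freq1 = tokens.build_freq_table(streams1)
    stage1_total = freq1.token_total
    reports.append(
        StageReport(
            "tokenize+stopwords", raw_token_total, stage1_total,
            percent(stage1_total, raw_token_total, 2) if raw_token_total else None,
        )
    )

    streams2, freq2 = tokens.content_filter(
        streams1, freq1, min_len=config.content_min_len, min_freq=config.content_min_freq
    )
    reports.append(
        StageReport(
            "content-filter", stage1_total, freq2.token_total,
            percent(freq2.token_total, raw_token_total, 2) if raw_token_total else None,
        )
    )
    logger.info(
        "tokens: %d raw, %d stage-1, %d content-bearing (%d types)",
        raw_token_total, stage1_total, freq2.token_total, freq2.type_count,
    )

    bigrams = colloc_mod.build_ngrams(streams2, 2, span_messages=config.span_messages)
    trigrams = colloc_mod.build_ngrams(streams2, 3, span_messages=config.span_messages)
    top = colloc_mod.top_collocations(
        [bigrams, trigrams], freq2, k_per_type=config.k_per_type, min_count=config.min_count
    )
    reports.append(StageReport("collocate", bigrams.distinct + trigrams.distinct, len(top)))

    equiv = EquivalenceMap.from_file(config.equiv) if config.equiv else None
    keywords = extract_keywords(top, equiv)
    reports.append(StageReport("keywords", len(top), len(keywords)))

    retrieval_set = None
    table = None
    delivered = None
    if lexicon is None and config.lexicon:
        lexicon = load_lexicon(config.lexicon)
    if lexicon is not None:
        retrieval_set = retrieval.retrieve(
            clean, lexicon, categories=config.categories, max_gap=config.max_gap
        )
        table = retrieval.retrieval_report(retrieval_set)
        reports.append(
            StageReport("retrieve", len(clean), len(retrieval_set.aggregate("either")))
        )
        if config.outdir:
            delivered = retrieval.deliver(
                retrieval_set, {m.id: m for m in clean}, config.outdir
            )

    participation = None
    if len(corpus):
        participation = participation_distribution(
            corpus, total_subscribers=config.total_subscribers
        )

    return PipelineResult(
        corpus=corpus,
        clean=clean,
        streams_stage1=streams1,
        freq_stage1=freq1,
        streams_content=streams2,
        freq_content=freq2,
        bigrams=bigrams,
        trigrams=trigrams,
        collocations=top,
        keywords=keywords,
        retrieval_set=retrieval_set,
        report_table=table,
        stage_reports=reports,
        delivered=delivered,
        participation=participation,
    )
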