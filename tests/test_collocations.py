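"""N-gram tables and PMI scoring, checked against brute-force enumeration."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from clinicolloc.collocations import (
    NGramTable,
    build_ngrams,
    pmi,
    top_collocations,
)
from clinicolloc.tokens import TokenStream, build_freq_table


def streams_from(*wordlists):
    return [
        TokenStream(i + 1, [(w, j * 10) for j, w in enumerate(words)])
        for i, words in enumerate(wordlists)
    ]


def brute_force_pmi(wordlists, words, n):
    """Independent oracle: enumerate windows and unigrams directly."""
    windows = []
    unigrams = []
    for wl in wordlists:
        unigrams.extend(wl)
        windows.extend(tuple(wl[i : i + n]) for i in range(len(wl) - n + 1))
    T = len(unigrams)
    W = len(windows)
    p_ngram = Counter(windows)[tuple(words)] / W
    p_indep = 1.0
    for w in words:
        p_indep *= Counter(unigrams)[w] / T
    return math.log2(p_ngram / p_indep)


class TestBuildNgrams:
    def test_contiguous_windows(self):
        table = build_ngrams(streams_from(["a", "b", "c", "d"]), 2)
        assert table.counts == Counter({("a", "b"): 1, ("b", "c"): 1, ("c", "d"): 1})
        assert table.window_total == 3

    def test_no_cross_message_windows(self):
        table = build_ngrams(streams_from(["a", "b"], ["c", "d"]), 2)
        assert ("b", "c") not in table
        assert table.counts == Counter({("a", "b"): 1, ("c", "d"): 1})

    def test_span_messages_merges_streams(self):
        table = build_ngrams(streams_from(["a", "b"], ["c", "d"]), 2, span_messages=True)
        assert table[("b", "c")] == 1 and table.window_total == 3

    def test_repeated_ngrams_counted(self):
        table = build_ngrams(streams_from(["a", "b", "a", "b"]), 2)
        assert table[("a", "b")] == 2 and table[("b", "a")] == 1

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError):
            build_ngrams(streams_from(["a", "b"]), 4)

    def test_window_total_formula(self):
        wls = [["a"] * 5, ["b"] * 2, ["c"]]
        table = build_ngrams(streams_from(*wls), 3)
        assert table.window_total == sum(max(0, len(w) - 2) for w in wls)


class TestPMI:
    def test_independence_limit_is_zero(self):
        # c12/W == (c1/T)(c2/T): 1/4 == (4/8)*(4/8) with hand-built tables
        table = NGramTable(n=2, counts=Counter({("a", "b"): 1}), window_total=4)
        freq = build_freq_table(streams_from(["a"] * 4 + ["b"] * 4))
        assert pmi(("a", "b"), table, freq) == pytest.approx(0.0)

    def test_hand_computed_bigram(self):
        # T=10 tokens, W=9 windows, c(oral)=3, c(lesion)=2, c(oral,lesion)=2
        table = NGramTable(n=2, counts=Counter({("oral", "lesion"): 2}), window_total=9)
        freq = build_freq_table(
            streams_from(["oral"] * 3 + ["lesion"] * 2 + ["x"] * 5)
        )
        expected = math.log2((2 / 9) / (0.3 * 0.2))
        assert pmi(("oral", "lesion"), table, freq) == pytest.approx(expected)
        assert expected == pytest.approx(1.889, abs=5e-4)

    def test_matches_brute_force_on_enumerated_stream(self):
        wordlists = [["oral", "lesion", "oral", "biopsy", "oral", "lesion"],
                     ["biopsy", "margin", "oral", "lesion", "margin"]]
        for n in (2, 3):
            table = build_ngrams(streams_from(*wordlists), n)
            freq = build_freq_table(streams_from(*wordlists))
            for words in table.counts:
                assert pmi(words, table, freq) == pytest.approx(
                    brute_force_pmi(wordlists, words, n)
                )

    def test_missing_ngram_rejected(self):
        table = build_ngrams(streams_from(["a", "b"]), 2)
        freq = build_freq_table(streams_from(["a", "b"]))
        with pytest.raises(ValueError):
            pmi(("b", "a"), table, freq)

    def test_symmetric_in_unigram_marginals(self):
        """Swapping word identities with identical counts gives equal scores."""
        freq = build_freq_table(streams_from(["u"] * 3 + ["v"] * 3 + ["w"] * 4))
        table = NGramTable(
            n=2, counts=Counter({("u", "v"): 2, ("v", "u"): 2}), window_total=9
        )
        assert pmi(("u", "v"), table, freq) == pytest.approx(pmi(("v", "u"), table, freq))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(2, 20), st.integers(1, 10), st.integers(1, 10), st.integers(1, 5))
    def test_scale_invariance(self, scale, c1, c2, c12):
        """Scaling all counts and totals identically leaves PMI unchanged."""
        c12 = min(c12, c1, c2)
        T, W = 100, 99
        t1 = NGramTable(2, Counter({("a", "b"): c12}), window_total=W)
        f1 = FreqLike({"a": c1, "b": c2}, T)
        t2 = NGramTable(2, Counter({("a", "b"): c12 * scale}), window_total=W * scale)
        f2 = FreqLike({"a": c1 * scale, "b": c2 * scale}, T * scale)
        assert pmi(("a", "b"), t1, f1) == pytest.approx(pmi(("a", "b"), t2, f2))


class FreqLike:
    """Minimal frequency-table stand-in with an explicit token total."""

    def __init__(self, counts, total):
        self._c = counts
        self.token_total = total

    def __getitem__(self, w):
        return self._c.get(w, 0)


class TestTopCollocations:
    def test_empty_tables(self):
        freq = build_freq_table([])
        out = top_collocations(
            [NGramTable(2, Counter(), 0), NGramTable(3, Counter(), 0)], freq
        )
        assert out == []

    def test_fewer_candidates_than_k_returns_all(self):
        streams = streams_from(["a", "b", "a", "b", "c", "a", "b"])
        table = build_ngrams(streams, 2)
        freq = build_freq_table(streams)
        out = top_collocations([table], freq, k_per_type=300, min_count=2)
        assert [sc.words for sc in out] == [("a", "b")]  # only repeated bigram

    def test_planted_adjacent_pair_outranks_frequent_independents(self):
        # "herpes zoster" always adjacent; "filler" and "common" frequent but
        # independently scattered
        wordlists = [
            ["herpes", "zoster", "filler", "common"],
            ["common", "filler", "herpes", "zoster"],
            ["filler", "common", "filler", "common"],
            ["herpes", "zoster", "common", "filler"],
        ]
        streams = streams_from(*wordlists)
        table = build_ngrams(streams, 2)
        freq = build_freq_table(streams)
        out = top_collocations([table], freq, k_per_type=5, min_count=2)
        assert out[0].words == ("herpes", "zoster")
        # oracle agreement for the winner
        assert out[0].pmi == pytest.approx(
            brute_force_pmi(wordlists, ("herpes", "zoster"), 2)
        )

    def test_words_closed_under_content_vocabulary(self, small_sim, sim_lexicon):
        from clinicolloc import clean_corpus, content_filter, build_freq_table as bft
        from clinicolloc import tokenize_corpus

        _, corpus, _ = small_sim
        clean = clean_corpus(corpus)
        streams = tokenize_corpus(clean)
        freq1 = bft(streams)
        streams2, freq2 = content_filter(streams, freq1)
        bigrams = build_ngrams(streams2, 2)
        trigrams = build_ngrams(streams2, 3)
        out = top_collocations([bigrams, trigrams], freq2, k_per_type=50)
        assert out, "synthetic corpus should yield collocation candidates"
        for sc in out:
            for w in sc.words:
                assert w in freq2
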