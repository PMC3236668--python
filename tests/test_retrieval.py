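"""Proximity matching, gap boundaries, folder semantics, and delivery."""

import pytest

from clinicolloc.lexicon import Category, Lexicon
from clinicolloc.retrieval import (
    KeywordQuery,
    build_keyword_queries,
    compile_phrase_query,
    deliver,
    match_message,
    retrieval_report,
    retrieve,
)

from conftest import cm


def lex_of(**cats):
    lex = Lexicon()
    for name, (phrases, keywords) in cats.items():
        name = name.replace("_", " ")
        lex.categories[name] = Category(name=name, phrases=phrases, keywords=keywords)
    return lex


class TestCompile:
    def test_order_free_set_with_gap(self):
        q = compile_phrase_query(("herpes", "zoster"))
        assert q.words == frozenset({"herpes", "zoster"}) and q.max_gap == 100

    @pytest.mark.parametrize("phrase", [("one",), ("a", "b", "c", "d")])
    def test_wrong_arity_rejected(self, phrase):
        with pytest.raises(ValueError):
            compile_phrase_query(phrase)

    def test_adjacent_keywords_concatenated_in_order(self):
        qs = build_keyword_queries(
            ["mutans", "streptococci"], [("mutans", "streptococci", "presence")]
        )
        terms = [q.term for q in qs]
        assert terms == ["mutans", "streptococci", "mutans streptococci"]


class TestMatchPhrase:
    def test_order_ignored(self):
        q = compile_phrase_query(("mutans", "streptococci"))
        hits = match_message(cm(1, "the streptococci mutans finding"), q)
        assert len(hits) == 1

    def test_empty_message(self):
        q = compile_phrase_query(("herpes", "zoster"))
        assert match_message(cm(1, ""), q) == []

    @pytest.mark.parametrize("gap,expected", [(100, 1), (101, 0)])
    def test_gap_boundary_inclusive_at_100(self, gap, expected):
        filler = "." * gap
        q = compile_phrase_query(("herpes", "zoster"))
        hits = match_message(cm(1, f"herpes{filler}zoster"), q)
        assert len(hits) == expected

    def test_excerpt_with_interleaved_words_matches(self):
        text = (
            "If you have a tooth with an actively draining fistula (pus filled "
            "canal), do you do one visit endo if you can get a dry canal before "
            "obturation? Or do you medicate for some time period."
        )
        q = compile_phrase_query(("fistula", "filled", "obturation"))
        assert len(match_message(cm(1, text), q)) >= 1

    def test_whole_word_only(self):
        q = compile_phrase_query(("plaque", "formation"))
        assert match_message(cm(1, "plaques formation study"), q) == []

    def test_leftmost_nonoverlapping_instances(self):
        text = "herpes near zoster then herpes again zoster"
        q = compile_phrase_query(("herpes", "zoster"))
        hits = match_message(cm(1, text), q)
        assert len(hits) == 2
        assert hits[0].spans[0][0] < hits[1].spans[0][0]

    def test_gap_bookkeeping_inclusive_and_stripped(self):
        text = "herpes of the .. zoster"
        q = compile_phrase_query(("herpes", "zoster"))
        (hit,) = match_message(cm(1, text), q)
        assert hit.gaps == [len(" of the .. ")]
        assert hit.stripped_gaps == [5]  # "ofthe"

    def test_window_uses_later_duplicate_when_needed(self):
        # the earliest middle-word occurrence leaves the last word out of
        # reach; a valid chain exists only through the later duplicate
        chars = ["."] * 201
        chars[0], chars[5], chars[98], chars[199] = "a", "b", "b", "c"
        text = "".join(chars)
        q = compile_phrase_query(("a", "b", "c"))
        hits = match_message(cm(1, text), q)
        assert len(hits) == 1
        assert hits[0].spans == [(0, 1), (98, 99), (199, 200)]

    def test_monotone_in_max_gap(self):
        text = "herpes " + "y" * 60 + " zoster"
        for small, large in [(10, 70), (0, 100)]:
            small_hits = match_message(cm(1, text), compile_phrase_query(("herpes", "zoster"), small))
            large_hits = match_message(cm(1, text), compile_phrase_query(("herpes", "zoster"), large))
            assert len(small_hits) <= len(large_hits)


class TestMatchKeyword:
    def test_each_occurrence_is_an_instance(self):
        hits = match_message(cm(1, "mercury here, mercury there"), KeywordQuery("mercury"))
        assert len(hits) == 2

    def test_concatenated_term_preserves_order(self):
        q = KeywordQuery("mutans streptococci")
        assert len(match_message(cm(1, "mutans streptococci count"), q)) == 1
        assert match_message(cm(1, "streptococci mutans count"), q) == []

    def test_case_insensitive_whole_word(self):
        assert len(match_message(cm(1, "Mercury rising"), KeywordQuery("mercury"))) == 1
        assert match_message(cm(1, "mercurial"), KeywordQuery("mercury")) == []


class TestRetrieve:
    LEX = lex_of(
        systemic_disease=([("herpes", "zoster")], ["mercury"]),
        medication=([("intravenous", "bisphosphonates")], []),
    )

    def test_no_matches_all_folders_empty(self):
        rs = retrieve([cm(1, "nothing clinical")], self.LEX)
        assert all(not ids for ids in rs.folders.values())

    def test_unknown_category_rejected(self):
        with pytest.raises(KeyError):
            retrieve([cm(1, "x")], self.LEX, categories=["orthodontics"])

    def test_planted_messages_land_in_category_folder(self):
        msgs = [
            cm(1, "no match"),
            cm(3, "herpes then zoster close"),
            cm(7, "zoster before herpes"),
        ]
        rs = retrieve(msgs, self.LEX)
        assert rs.folder("systemic disease", "phrase") == {3, 7}

    def test_message_in_two_categories_counted_once_each(self):
        msgs = [cm(1, "herpes zoster with intravenous bisphosphonates")]
        rs = retrieve(msgs, self.LEX)
        assert rs.folder("systemic disease", "phrase") == {1}
        assert rs.folder("medication", "phrase") == {1}
        assert rs.aggregate("phrase") == {1}

    def test_retrieve_is_deterministic(self):
        msgs = [cm(1, "herpes zoster"), cm(2, "mercury mercury")]
        a, b = retrieve(msgs, self.LEX), retrieve(msgs, self.LEX)
        assert a.folders == b.folders and a.instance_counts == b.instance_counts

    def test_keyword_superset_of_phrase_keyword_messages(self):
        lex = lex_of(systemic_disease=([("mercury", "toxicity")], ["mercury"]))
        msgs = [cm(1, "mercury toxicity case"), cm(2, "plain mercury case")]
        rs = retrieve(msgs, lex)
        assert rs.folder("systemic disease", "phrase") <= rs.folder("systemic disease", "keyword")


class TestReportAndDeliver:
    LEX = TestRetrieve.LEX

    def test_empty_set_all_zero(self):
        rs = retrieve([cm(1, "nothing clinical here")], self.LEX)
        df = retrieval_report(rs)
        assert (df.drop(columns="category").to_numpy() == 0).all()

    def test_totals_sum_instances_dedupe_messages(self):
        msgs = [
            cm(1, "herpes zoster and intravenous bisphosphonates"),
            cm(2, "herpes zoster only"),
            cm(3, "mercury mercury"),
        ]
        rs = retrieve(msgs, self.LEX)
        df = retrieval_report(rs).set_index("category")
        total = df.loc["Total"]
        assert total.phrase_instances == df.drop("Total").phrase_instances.sum()
        assert total.phrase_messages == 2  # message 1 deduplicated across categories
        assert total.either_messages == 3

    def test_deliver_tree_counts_match_folders(self, tmp_path):
        msgs = [cm(1, "herpes zoster"), cm(2, "mercury")]
        rs = retrieve(msgs, self.LEX)
        written = deliver(rs, {m.id: m for m in msgs}, tmp_path)
        for rel, n in written.items():
            files = list((tmp_path / rel).glob("*.txt"))
            assert len(files) == n
        assert written["systemic_disease/phrase"] == 1
        assert written["_all_either"] == 2
        # same message, same filename, in two folders with identical content
        p1 = tmp_path / "systemic_disease/phrase/20081103_1.txt"
        p2 = tmp_path / "_all_phrase/20081103_1.txt"
        assert p1.read_text() == p2.read_text()
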