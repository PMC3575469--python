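"""Dictionary matching, flanking expansion and the stop-word review loop."""

import pytest

from proofer import (
    Lexicon,
    StopWordTable,
    match_terms,
    ocr_fold,
    propose_candidates,
    record_decision,
    run_session,
)
from proofer.engine import accept_terms, decisions_from_file, reject_all
from proofer.segmentation import SMALL_WORD_MAX_LEN


class TestMatching:
    def test_multiword_label_wins_over_nothing(self, anatomy_lexicon):
        m = match_terms(("a1", "propleural arm muscle"), anatomy_lexicon)
        assert [h.term.label for h in m.hits] == ["propleural arm"]
        assert [t.norm for t in m.unmatched_words] == ["muscle"]

    def test_longest_match_first(self):
        lex = Lexicon()
        lex.add_term("propleural")
        lex.add_term("propleural arm")
        m = match_terms(("a1", "the propleural arm here"), lex)
        assert [h.term.label for h in m.hits] == ["propleural arm"]

    def test_empty_lexicon_leaves_all_long_words_unmatched(self):
        m = match_terms(("a1", "mesopleuron smooth, with a deep groove"), Lexicon())
        assert m.hits == []
        assert [t.norm for t in m.unmatched_words] == [
            "mesopleuron", "smooth", "with", "deep", "groove",
        ]

    def test_matches_do_not_cross_punctuation(self):
        lex = Lexicon()
        lex.add_term("propleural arm")
        m = match_terms(("a1", "propleural, arm"), lex)
        assert m.hits == []

    def test_plural_and_synonym_surfaces_hit_canonical_term(self, anatomy_lexicon):
        m = match_terms(("a1", "terga smooth, tergite dark, carinae distinct"), anatomy_lexicon)
        assert sorted(h.term.label for h in m.hits) == ["carina", "tergum", "tergum"]

    def test_hit_spans_recover_surface_text(self, anatomy_lexicon):
        text = "The Propleural  arm is shiny."
        m = match_terms(("a1", text), anatomy_lexicon)
        hit = next(h for h in m.hits if h.term.label == "propleural arm")
        assert text[hit.span[0] : hit.span[1]] == "Propleural  arm"

    def test_conservation_of_phrase_words(self, anatomy_lexicon):
        text = "Mesoscutum smooth and shiny, with carina near the propleural arm muscle."
        m = match_terms(("a1", text), anatomy_lexicon)
        from proofer.segmentation import sentence_tokens, split_clauses
        phrase_words = sum(
            1
            for sent in sentence_tokens(text)
            for clause in split_clauses(sent)
            for t in clause
            if len(t.norm) > SMALL_WORD_MAX_LEN
        )
        assert m.covered_word_count() + len(m.unmatched_words) == phrase_words

    def test_hit_spans_non_overlapping(self, anatomy_lexicon):
        m = match_terms(("a1", "carina carina tergum mesoscutum"), anatomy_lexicon)
        spans = sorted(h.span for h in m.hits)
        assert all(s1[1] <= s2[0] for s1, s2 in zip(spans, spans[1:]))


class TestOcrTolerance:
    def test_digit_for_letter_confusion(self):
        lex = Lexicon()
        lex.add_term("clypeus")
        m = match_terms(("a1", "the c1ypeus is dark"), lex, ocr_tolerance=True)
        assert [h.term.label for h in m.hits] == ["clypeus"]
        assert match_terms(("a1", "the c1ypeus is dark"), lex).hits == []

    @pytest.mark.parametrize(
        "corrupt,clean",
        [("c1ypeus", "clypeus"), ("pr0n0tum", "pronotum"), ("carirna", "carima")],
    )
    def test_fold_canonicalizes_both_directions(self, corrupt, clean):
        assert ocr_fold(corrupt) == ocr_fold(clean)

    def test_tolerant_index_follows_lexicon_growth(self):
        lex = Lexicon()
        lex.add_term("clypeus")
        assert match_terms(("a1", "ga1ea"), lex, ocr_tolerance=True).hits == []
        lex.add_term("galea")
        m = match_terms(("a1", "ga1ea"), lex, ocr_tolerance=True)
        assert [h.term.label for h in m.hits] == ["galea"]


class TestCandidates:
    def test_flanking_expansion_reaches_multiword_label(self, anatomy_lexicon):
        m = match_terms(("a1", "the propleural arm muscle."), anatomy_lexicon)
        cands = propose_candidates(m, StopWordTable())
        muscle = next(c for c in cands if c.seed_word == "muscle")
        assert "propleural arm muscle" in muscle.expansions
        assert all(
            phrase.split(" ").__len__() == k + 1
            for k, phrase in enumerate(muscle.expansions, start=1)
        )

    def test_expansions_prefer_following_words(self):
        m = match_terms(("a1", "deep groove near the margin"), Lexicon())
        cands = propose_candidates(m, StopWordTable())
        deep = next(c for c in cands if c.seed_word == "deep")
        assert deep.expansions[0] == "deep groove"
        assert deep.expansions[-1] == "deep groove near the margin"

    def test_all_words_matched_yields_no_candidates(self, anatomy_lexicon):
        m = match_terms(("a1", "carina and tergum."), anatomy_lexicon)
        assert propose_candidates(m, StopWordTable()) == []

    def test_finalized_stop_word_not_proposed(self):
        m = match_terms(("a11", "very deep groove"), Lexicon())
        table = StopWordTable()
        for i in range(10):
            table.reject("groove", f"art{i}")
        seeds = {c.seed_word for c in propose_candidates(m, table)}
        assert "groove" not in seeds
        assert "deep" in seeds

    def test_candidate_set_shrinks_with_stop_list(self):
        m = match_terms(("a1", "mesopleuron smooth with deep groove"), Lexicon())
        empty = {c.seed_word for c in propose_candidates(m, StopWordTable())}
        table = StopWordTable(threshold=1)
        table.reject("smooth", "other")
        shrunk = {c.seed_word for c in propose_candidates(m, table)}
        assert shrunk <= empty
        assert "smooth" not in shrunk

    def test_max_flank_bounds(self):
        m = match_terms(("a1", "one word"), Lexicon())
        with pytest.raises(ValueError):
            propose_candidates(m, StopWordTable(), max_flank=0)
        with pytest.raises(ValueError):
            propose_candidates(m, StopWordTable(), max_flank=6)


class TestStopWords:
    def test_finalizes_at_exactly_ten_distinct_articles(self):
        table = StopWordTable()
        for i in range(9):
            assert table.reject("large", f"art{i}") is False
        assert not table.is_finalized("large")
        assert table.reject("large", "art9") is True
        assert table.is_finalized("large")

    def test_repeat_rejection_from_same_article_is_noop(self):
        table = StopWordTable()
        table.reject("large", "art0")
        table.reject("large", "art0")
        assert table.rejection_count("large") == 1

    def test_save_load_round_trip(self, tmp_path):
        table = StopWordTable()
        for i in range(10):
            table.reject("large", f"art{i}")
        table.reject("deep", "art0")
        path = tmp_path / "stop.tsv"
        table.save(path)
        loaded = StopWordTable.load(path)
        assert loaded.is_finalized("large")
        assert loaded.rejection_count("deep") == 1
        assert loaded.rejecting_articles("large") == table.rejecting_articles("large")


class TestDecisions:
    def test_accept_adds_tagged_discovered_term(self):
        lex, table = Lexicon(), StopWordTable()
        record_decision("propleural arm muscle", "accept", "a1", lex, table,
                        tags={"JHR-BHL"})
        term = lex.lookup("propleural arm muscle")
        assert term is not None and "JHR-BHL" in term.tags

    def test_reject_phrase_penalizes_only_seed(self):
        lex, table = Lexicon(), StopWordTable()
        record_decision("deep groove", "reject", "a1", lex, table, seed_word="groove")
        assert table.rejection_count("groove") == 1
        assert table.rejection_count("deep") == 0

    def test_invalid_decision_rejected(self):
        with pytest.raises(ValueError):
            record_decision("word", "maybe", "a1", Lexicon(), StopWordTable())


class TestSessions:
    def corpus_with_shared_noise(self, n=12):
        return {
            f"art{i:02d}": f"Unknownword here. The fovea{i} is distinct."
            for i in range(n)
        }

    def test_shared_noise_word_finalizes_and_disappears(self):
        corpus = self.corpus_with_shared_noise()
        report = run_session(corpus, Lexicon(), StopWordTable(), reject_all)
        shown = [a.candidates_shown_with_stoplist for a in report.articles]
        without = [a.candidates_without_stoplist for a in report.articles]
        # once 10 articles rejected the recurring words, later articles show
        # fewer candidates than the no-stop-list baseline
        assert shown[-1] < without[-1]
        assert report.articles[-1].stop_words_finalized > 0

    def test_accepted_term_becomes_a_hit_in_later_articles(self):
        corpus = {
            "a1": "The propleural arm muscle is large.",
            "a2": "Another propleural arm muscle here.",
        }
        lex = Lexicon()
        lex.add_term("propleural arm")
        report = run_session(
            corpus, lex, StopWordTable(), accept_terms(["propleural arm muscle"])
        )
        assert "propleural arm muscle" in report.accepted_terms
        m2 = match_terms(("a2", corpus["a2"]), lex)
        assert "propleural arm muscle" in m2.hit_terms()

    def test_empty_corpus_empty_report(self):
        report = run_session({}, Lexicon(), StopWordTable(), reject_all)
        assert report.articles == [] and report.errors == []

    def test_checkpoints_written_per_article(self, tmp_path):
        corpus = {"a1": "fovea distinct.", "a2": "scrobe deep."}
        run_session(corpus, Lexicon(), StopWordTable(), reject_all,
                    checkpoint_dir=tmp_path)
        assert (tmp_path / "lexicon.tsv").exists()
        assert (tmp_path / "stopwords.tsv").exists()

    def test_scripted_decision_file(self, tmp_path):
        decisions = tmp_path / "decisions.tsv"
        decisions.write_text("a1\tfovea distinct\taccept\n")
        corpus = {"a1": "The fovea distinct thing."}
        lex = Lexicon()
        run_session(corpus, lex, StopWordTable(), decisions_from_file(decisions))
        assert lex.lookup("fovea distinct") is not None
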