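"""The term-discovery engine: dictionary matching over OCR text, candidate
proposal with flanking expansion, and the active-learning stop-word loop.

Matching is greedy longest-first within each punctuation-delimited clause:
at every position the longest indexed surface form wins, so "propleural arm"
is preferred over "propleural" when both are known. OCR tolerance is a
deterministic substitution table (1<->l, 0<->o, rn<->m, vv<->w, e-acute->e)
applied to both the index keys and the query token, so either direction of a
confusion matches.

Every word a reviewer rejects is tallied per article; once 10 distinct
articles have rejected a word it is finalized as a stop word and never
offered again, shrinking the review workload as a session progresses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .lexicon import Lexicon, Term, TermKind, TermSource, normalize
from .segmentation import (
    SMALL_WORD_MAX_LEN,
    ArticleText,
    Token,
    segment_article,
    sentence_tokens,
    split_clauses,
    read_corpus,
)

__all__ = [
    "OCR_SUBSTITUTIONS",
    "ocr_fold",
    "MatchResult",
    "TermHit",
    "CandidatePhrase",
    "StopWordTable",
    "match_terms",
    "propose_candidates",
    "record_decision",
    "run_session",
    "SessionReport",
]

logger = logging.getLogger("proofer")

#: Character confusions commonly produced by OCR of printed taxonomic text.
#: Each pair is folded to one canonical side on both the index and the query,
#: so matching tolerates either direction.
OCR_SUBSTITUTIONS: tuple[tuple[str, str], ...] = (
    ("1", "l"),
    ("0", "o"),
    ("rn", "m"),
    ("vv", "w"),
    ("é", "e"),
)

#: Default number of distinct rejecting articles that finalizes a stop word.
STOP_WORD_THRESHOLD = 10

MAX_FLANK = 5


def ocr_fold(s: str, table: tuple[tuple[str, str], ...] = OCR_SUBSTITUTIONS) -> str:
    """Canonical form of ``s`` under the OCR confusion table."""
    for bad, good in table:
        s = s.replace(bad, good)
    return s


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermHit:
    term: Term
    span: tuple[int, int]
    surface: str


@dataclass
class MatchResult:
    """Hits and leftover words for one article.

    ``unmatched_words`` lists the phrase-eligible tokens (normalized length
    > 3) not covered by any hit; short connectives are never candidates.
    ``clauses`` retains the clause context needed for flanking expansion.
    """

    article_id: str
    hits: list[TermHit] = field(default_factory=list)
    unmatched_words: list[Token] = field(default_factory=list)
    clauses: list[list[Token]] = field(default_factory=list)
    _unmatched_pos: list[tuple[int, int]] = field(default_factory=list)

    def hit_terms(self) -> set[str]:
        return {h.term.label for h in self.hits}

    def covered_word_count(self) -> int:
        """Number of phrase-eligible tokens covered by hits."""
        return self._covered

    _covered: int = 0


class _FoldIndex:
    """OCR-folded view of a lexicon index, rebuilt lazily when the lexicon
    grows (terms accepted mid-session)."""

    def __init__(self, lexicon: Lexicon, table: tuple[tuple[str, str], ...]):
        self._lexicon = lexicon
        self._table = table
        self._size = -1
        self._folded: dict[str, Term] = {}

    def lookup(self, form: str) -> Term | None:
        index = self._lexicon.index
        if len(index) != self._size:
            self._folded = {}
            for key, term in index.items():
                self._folded.setdefault(ocr_fold(key, self._table), term)
            self._size = len(index)
        return self._folded.get(ocr_fold(form, self._table))


def match_terms(
    article: ArticleText | tuple[str, str],
    lexicon: Lexicon,
    ocr_tolerance: bool = False,
    substitutions: tuple[tuple[str, str], ...] = OCR_SUBSTITUTIONS,
) -> MatchResult:
    """Greedy longest-match-first dictionary matching over one article."""
    if not isinstance(article, ArticleText):
        article = segment_article(*article)
    fold_index = _FoldIndex(lexicon, substitutions) if ocr_tolerance else None
    result = MatchResult(article_id=article.article_id)
    covered = 0

    for sent in sentence_tokens(article.raw_text):
        for clause in split_clauses(sent):
            result.clauses.append(clause)
            ci = len(result.clauses) - 1
            i = 0
            n = len(clause)
            while i < n:
                hit_term = None
                hit_len = 0
                max_w = min(lexicon.max_words, n - i)
                for w in range(max_w, 0, -1):
                    form = " ".join(t.norm for t in clause[i : i + w])
                    term = lexicon.lookup_normalized(form)
                    if term is None and fold_index is not None:
                        term = fold_index.lookup(form)
                    if term is not None:
                        hit_term, hit_len = term, w
                        break
                if hit_term is not None:
                    toks = clause[i : i + hit_len]
                    result.hits.append(
                        TermHit(
                            term=hit_term,
                            span=(toks[0].start, toks[-1].end),
                            surface=" ".join(t.surface for t in toks),
                        )
                    )
                    covered += sum(1 for t in toks if len(t.norm) > SMALL_WORD_MAX_LEN)
                    i += hit_len
                else:
                    tok = clause[i]
                    if len(tok.norm) > SMALL_WORD_MAX_LEN:
                        result.unmatched_words.append(tok)
                        result._unmatched_pos.append((ci, i))
                    i += 1
    result._covered = covered
    return result


# ---------------------------------------------------------------------------
# candidate proposal
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidatePhrase:
    """An unmatched seed word plus its flanking expansions.

    ``expansions[k-1]`` contains the seed plus ``k`` flanking words from the
    same clause, preferring the words on the left of the seed (so a known
    label ending at the seed, like "propleural arm" before "muscle", is
    completed first) and falling back to following words when the seed sits
    near the clause start; word order is clause order.
    """

    seed_word: str
    expansions: tuple[str, ...]
    article_id: str

    def all_phrases(self) -> tuple[str, ...]:
        return (self.seed_word, *self.expansions)


def _expansions(clause: list[Token], idx: int, max_flank: int) -> tuple[str, ...]:
    out: list[str] = []
    seen: set[str] = set()
    limit = min(max_flank, len(clause) - 1)
    for k in range(1, limit + 1):
        nprev = min(k, idx)
        nfollow = k - nprev
        words = clause[idx - nprev : idx + nfollow + 1]
        phrase = " ".join(t.norm for t in words)
        if phrase not in seen:
            seen.add(phrase)
            out.append(phrase)
    return tuple(out)


def propose_candidates(
    match: MatchResult,
    stop_words: "StopWordTable",
    max_flank: int = MAX_FLANK,
) -> list[CandidatePhrase]:
    """One candidate per distinct unmatched, non-finalized word, in order of
    first occurrence in the article."""
    if not 1 <= max_flank <= MAX_FLANK:
        raise ValueError(f"max_flank must be in 1..{MAX_FLANK}, got {max_flank}")
    candidates: list[CandidatePhrase] = []
    seen_seeds: set[str] = set()
    for tok, (ci, idx) in zip(match.unmatched_words, match._unmatched_pos):
        seed = tok.norm
        if seed in seen_seeds or stop_words.is_finalized(seed):
            continue
        seen_seeds.add(seed)
        candidates.append(
            CandidatePhrase(
                seed_word=seed,
                expansions=_expansions(match.clauses[ci], idx, max_flank),
                article_id=match.article_id,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# stop words and decisions
# ---------------------------------------------------------------------------


class StopWordTable:
    """Per-word rejection tally with one vote per article.

    A word is *finalized* once ``threshold`` distinct articles have rejected
    it; finalized words are never proposed again.
    """

    def __init__(self, threshold: int = STOP_WORD_THRESHOLD) -> None:
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold
        self._entries: dict[str, set[str]] = {}

    def reject(self, word: str, article_id: str) -> bool:
        """Record a rejection; returns True if the word is now finalized.
        A repeat rejection from the same article is a no-op."""
        word = normalize(word)
        self._entries.setdefault(word, set()).add(article_id)
        return self.is_finalized(word)

    def rejection_count(self, word: str) -> int:
        return len(self._entries.get(normalize(word), ()))

    def rejecting_articles(self, word: str) -> frozenset[str]:
        return frozenset(self._entries.get(normalize(word), ()))

    def is_finalized(self, word: str) -> bool:
        return len(self._entries.get(normalize(word), ())) >= self.threshold

    def finalized_words(self) -> set[str]:
        return {w for w, arts in self._entries.items() if len(arts) >= self.threshold}

    def __len__(self) -> int:
        return len(self._entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self._entries):
                arts = sorted(self._entries[word])
                fh.write(
                    f"{word}\t{len(arts)}\t{str(self.is_finalized(word)).lower()}"
                    f"\t{','.join(arts)}\n"
                )

    @classmethod
    def load(cls, path: str | Path, threshold: int = STOP_WORD_THRESHOLD) -> "StopWordTable":
        table = cls(threshold=threshold)
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                word, _count, _final, arts = (line.split("\t") + [""])[:4]
                table._entries[word] = {a for a in arts.split(",") if a}
        return table


def record_decision(
    word_or_phrase: str,
    decision: str,
    article_id: str,
    lexicon: Lexicon,
    stop_words: StopWordTable,
    tags: Iterable[str] = (),
    seed_word: str | None = None,
    kind: TermKind = TermKind.MORPHOLOGICAL,
) -> tuple[Lexicon, StopWordTable]:
    """Apply one reviewer decision.

    Accepting adds the phrase to the lexicon as a discovered term with the
    given tags. Rejecting a multi-word phrase penalizes only its seed word
    (flanking words may be valid elsewhere); when no seed is supplied the
    final word of the phrase is used.
    """
    if decision not in ("accept", "reject"):
        raise ValueError(f"decision must be 'accept' or 'reject', got {decision!r}")
    phrase = normalize(word_or_phrase)
    if not phrase:
        raise ValueError(f"empty phrase {word_or_phrase!r}")
    if decision == "accept":
        lexicon.add_term(phrase, kind=kind, tags=tags, source=TermSource.DISCOVERED)
    else:
        seed = normalize(seed_word) if seed_word else phrase.split(" ")[-1]
        stop_words.reject(seed, article_id)
    return lexicon, stop_words


# ---------------------------------------------------------------------------
# review sessions
# ---------------------------------------------------------------------------

#: A decision source maps (article_id, candidate) to None (skip), or a tuple
#: ("accept", phrase-to-add) / ("reject", None).
DecisionSource = Callable[[str, CandidatePhrase], tuple[str, str | None] | None]


def reject_all(article_id: str, candidate: CandidatePhrase):
    """Scripted reviewer that rejects every seed (stop-word stress test)."""
    return ("reject", None)


def accept_terms(wanted: Iterable[str]) -> DecisionSource:
    """Scripted reviewer accepting any offered expansion found in ``wanted``
    (longest offered match wins) and rejecting everything else."""
    wanted_set = {normalize(w) for w in wanted}

    def source(article_id: str, candidate: CandidatePhrase):
        for phrase in sorted(candidate.all_phrases(), key=len, reverse=True):
            if phrase in wanted_set:
                return ("accept", phrase)
        return ("reject", None)

    return source


def decisions_from_file(path: str | Path) -> DecisionSource:
    """Reviewer scripted by a tab-separated file with columns
    article_id, phrase, decision; unlisted candidates are skipped."""
    table: dict[tuple[str, str], tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            article_id, phrase, decision = line.split("\t")[:3]
            for word in normalize(phrase).split(" "):
                table[(article_id, word)] = (decision.strip(), normalize(phrase))

    def source(article_id: str, candidate: CandidatePhrase):
        entry = table.get((article_id, candidate.seed_word))
        if entry is None:
            return None
        decision, phrase = entry
        return (decision, phrase if decision == "accept" else None)

    return source


@dataclass
class ArticleReport:
    article_id: str
    n_hits: int
    candidates_shown_with_stoplist: int
    candidates_without_stoplist: int
    n_accepted: int
    n_rejected: int
    stop_words_finalized: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SessionReport:
    articles: list[ArticleReport] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)
    accepted_terms: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "articles": [a.as_dict() for a in self.articles],
            "errors": self.errors,
            "accepted_terms": self.accepted_terms,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")


def run_session(
    corpus,
    lexicon: Lexicon,
    stop_words: StopWordTable,
    decision_source: DecisionSource,
    *,
    ocr_tolerance: bool = False,
    max_flank: int = MAX_FLANK,
    accept_tags: tuple[str, ...] = ("JHR-BHL",),
    checkpoint_dir: str | Path | None = None,
) -> SessionReport:
    """Process a corpus in order through match -> propose -> decide.

    Accepted terms enter the lexicon immediately and are matchable in every
    subsequent article; rejected seeds accumulate in the stop-word table.
    Per article the report records the candidate count both with the current
    stop list and with an empty one, so the workload reduction achieved by
    the active-learning loop is computable. Unreadable articles are logged,
    skipped and reported, not fatal.
    """
    report = SessionReport()
    empty_table = StopWordTable(threshold=stop_words.threshold)
    checkpoint = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if checkpoint is not None:
        checkpoint.mkdir(parents=True, exist_ok=True)

    if not isinstance(corpus, dict):
        corpus = read_corpus(corpus)

    for article_id, text in corpus.items():
        try:
            if isinstance(text, Exception):  # pragma: no cover - defensive
                raise text
            match = match_terms((article_id, text), lexicon, ocr_tolerance)
        except Exception as exc:
            logger.warning("skipping unreadable article %s: %s", article_id, exc)
            report.errors.append({"article_id": article_id, "error": str(exc)})
            continue

        candidates = propose_candidates(match, stop_words, max_flank)
        without_stoplist = propose_candidates(match, empty_table, max_flank)
        n_accept = n_reject = 0
        for cand in candidates:
            verdict = decision_source(article_id, cand)
            if verdict is None:
                continue
            decision, phrase = verdict
            record_decision(
                phrase if (decision == "accept" and phrase) else cand.seed_word,
                decision,
                article_id,
                lexicon,
                stop_words,
                tags=accept_tags,
                seed_word=cand.seed_word,
            )
            if decision == "accept":
                n_accept += 1
                report.accepted_terms.append(normalize(phrase or cand.seed_word))
            else:
                n_reject += 1

        report.articles.append(
            ArticleReport(
                article_id=article_id,
                n_hits=len(match.hits),
                candidates_shown_with_stoplist=len(candidates),
                candidates_without_stoplist=len(without_stoplist),
                n_accepted=n_accept,
                n_rejected=n_reject,
                stop_words_finalized=len(stop_words.finalized_words()),
            )
        )
        if checkpoint is not None:
            lexicon.save(checkpoint / "lexicon.tsv")
            stop_words.save(checkpoint / "stopwords.tsv")
    return report
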