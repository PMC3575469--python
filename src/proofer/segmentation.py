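"""Sentence, clause and phrase segmentation of (OCR) article text.

The candidate-proposal pipeline works on three nested units:

* **sentences** — split at '.', '!' or '?' followed by whitespace (no
  abbreviation handling; "Fig. 3" splits, a documented limitation);
* **clauses** — runs of word tokens between punctuation marks; terms are
  matched within clauses, so a multiword label may contain a short word
  ("propleural arm") but never a comma or period;
* **phrases** — clauses additionally split at small words (normalized length
  <= 3), with the small words removed. Phrases define which words are
  eligible as candidate seeds.

Tokens keep their character offsets into the raw text so hits can be
highlighted in the original OCR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .lexicon import normalize

__all__ = [
    "Token",
    "Phrase",
    "ArticleText",
    "tokenize",
    "split_sentences",
    "split_clauses",
    "segment_phrases",
    "segment_article",
    "read_corpus",
]

#: Closed set of splitting punctuation (the tokenizer treats each mark as its
#: own token and phrase/clause segmentation splits there).
PUNCTUATION = ".,;:()[]!?/"

SMALL_WORD_MAX_LEN = 3

_TOKEN_RE = re.compile(r"[.,;:()\[\]!?/]|[^\s.,;:()\[\]!?/]+")
_SENTENCE_END = re.compile(r"[.!?](?=\s|$)")


@dataclass(frozen=True)
class Token:
    surface: str
    norm: str          # lowercased, surrounding punctuation stripped
    start: int         # character offset into the raw text
    is_punct: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.surface)


@dataclass(frozen=True)
class Phrase:
    """Maximal run of long words: no punctuation, no token of length <= 3."""

    words: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("phrase must contain at least one word")

    @property
    def span(self) -> tuple[int, int]:
        return (self.words[0].start, self.words[-1].end)

    @property
    def text(self) -> str:
        return " ".join(t.norm for t in self.words)


@dataclass
class ArticleText:
    """One article: raw OCR text plus its word-token stream."""

    article_id: str
    raw_text: str
    tokens: list[Token] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = [t for t in tokenize(self.raw_text) if not t.is_punct]


def tokenize(text: str) -> list[Token]:
    """Word and punctuation tokens with offsets; empty norms are dropped
    unless the token is punctuation."""
    out: list[Token] = []
    for m in _TOKEN_RE.finditer(text):
        surface = m.group(0)
        if len(surface) == 1 and surface in PUNCTUATION:
            out.append(Token(surface, surface, m.start(), is_punct=True))
            continue
        norm = normalize(surface)
        if norm:
            out.append(Token(surface, norm, m.start()))
    return out


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences; boundaries at '.', '!', '?' followed by
    whitespace (or end of text). Spans cover all non-whitespace text."""
    if not text.strip():
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        end = m.end()
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def split_clauses(tokens: list[Token]) -> list[list[Token]]:
    """Split a token stream at punctuation marks; punctuation removed."""
    clauses: list[list[Token]] = []
    current: list[Token] = []
    for tok in tokens:
        if tok.is_punct:
            if current:
                clauses.append(current)
                current = []
        else:
            current.append(tok)
    if current:
        clauses.append(current)
    return clauses


def segment_phrases(tokens: list[Token]) -> list[Phrase]:
    """Split at punctuation and at small words (normalized length <= 3),
    removing the split tokens; empty fragments are dropped."""
    phrases: list[Phrase] = []
    current: list[Token] = []
    for tok in tokens:
        if tok.is_punct or len(tok.norm) <= SMALL_WORD_MAX_LEN:
            if current:
                phrases.append(Phrase(tuple(current)))
                current = []
        else:
            current.append(tok)
    if current:
        phrases.append(Phrase(tuple(current)))
    return phrases


def sentence_tokens(text: str) -> Iterator[list[Token]]:
    """Token streams (words + punctuation) per sentence."""
    for start, end in split_sentences(text):
        toks = tokenize(text[start:end])
        yield [
            Token(t.surface, t.norm, t.start + start, t.is_punct) for t in toks
        ]


def segment_article(article_id: str, raw_text: str) -> ArticleText:
    return ArticleText(article_id=article_id, raw_text=raw_text)


def read_corpus(source) -> dict[str, str]:
    """Materialize a corpus as an ordered {article_id: text} mapping.

    Accepts a mapping, a directory of ``<article_id>.txt`` files (sorted by
    id), or a tab-separated manifest mapping id -> path.
    """
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    if path.is_dir():
        return {
            p.stem: p.read_text(encoding="utf-8", errors="replace")
            for p in sorted(path.glob("*.txt"))
        }
    corpus: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            article_id, file_path = line.split("\t", 1)
            corpus[article_id] = Path(file_path).read_text(
                encoding="utf-8", errors="replace"
            )
    return corpus
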