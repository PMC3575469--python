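"""Binary term x article occurrence matrices.

Articles are the terminals (rows) and anatomical terms the characters
(columns); a cell is 1 when the term — via any surface form, synonyms and
plurals conflated — occurs in the article's text. Qualitative terms and an
explicit exclusion list ('cell', 'area', 'costa' in the original analysis)
are dropped, as are all-zero columns, which carry no signal and break the
denominators of several binary distance coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .engine import match_terms
from .lexicon import Lexicon, TermKind, normalize
from .segmentation import read_corpus

__all__ = [
    "OccurrenceMatrix",
    "build_matrix",
    "filter_by_occurrence",
    "rank_terms",
    "DEFAULT_EXCLUDED_TERMS",
]

logger = logging.getLogger("proofer")

#: Terms removed from the character list because they are common in other
#: disciplines and often non-morphological in context.
DEFAULT_EXCLUDED_TERMS = frozenset({"cell", "area", "costa"})

LABEL_COLUMNS = ("family", "superfamily", "descriptive")


@dataclass
class OccurrenceMatrix:
    """Binary presence/absence matrix with per-article taxon labels.

    ``binary``: DataFrame indexed by article id, columns = term labels,
    values in {0, 1}. ``counts`` optionally carries raw per-article
    occurrence counts (needed for total-occurrence ranking and the
    occurrence-count filter mode). ``labels``: DataFrame indexed by article
    id with columns family, superfamily, descriptive.
    """

    binary: pd.DataFrame
    labels: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.binary.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("occurrence matrix cells must be 0 or 1")
        self.binary = self.binary.astype(np.int8)
        if self.labels is not None:
            missing = [a for a in self.binary.index if a not in self.labels.index]
            if missing:
                logger.warning(
                    "articles without taxon labels (unusable for pruning): %s",
                    ", ".join(map(str, missing)),
                )

    @property
    def terms(self) -> list[str]:
        return list(self.binary.columns)

    @property
    def articles(self) -> list[str]:
        return list(self.binary.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.binary.shape

    def label_map(self, level: str) -> dict[str, str]:
        """Leaf -> group name at ``level`` ('family' or 'superfamily')."""
        if self.labels is None:
            raise ValueError("matrix carries no taxon labels")
        if level not in ("family", "superfamily"):
            raise ValueError(f"level must be 'family' or 'superfamily', got {level!r}")
        out: dict[str, str] = {}
        for article in self.articles:
            if article not in self.labels.index or pd.isna(self.labels.loc[article, level]):
                raise ValueError(f"article {article!r} has no {level} label")
            out[article] = str(self.labels.loc[article, level])
        return out

    # -- persistence --------------------------------------------------------

    def to_csv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        """Write the matrix (rows = articles, first column ``article_id``)
        and, when labels are present, a sidecar labels CSV."""
        out = self.binary.copy()
        out.insert(0, "article_id", out.index)
        out.to_csv(path, index=False)
        if self.labels is not None:
            if labels_path is None:
                p = Path(path)
                labels_path = p.with_name(p.stem + ".labels.csv")
            lab = self.labels.copy()
            lab.insert(0, "article_id", lab.index)
            lab.to_csv(labels_path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, labels_path: str | Path | None = None
    ) -> "OccurrenceMatrix":
        df = pd.read_csv(path, dtype={"article_id": str})
        df = df.set_index("article_id")
        df.index.name = None
        labels = None
        if labels_path is not None:
            labels = pd.read_csv(labels_path, dtype={"article_id": str}).set_index(
                "article_id"
            )
            labels.index.name = None
            if "descriptive" in labels.columns:
                labels["descriptive"] = labels["descriptive"].astype(bool)
        return cls(binary=df, labels=labels)


def build_matrix(
    corpus,
    lexicon: Lexicon,
    *,
    include_kinds: Iterable[TermKind] = (TermKind.MORPHOLOGICAL,),
    exclude_terms: Iterable[str] = (),
    metadata: pd.DataFrame | None = None,
    descriptive_only: bool = False,
    ocr_tolerance: bool = False,
) -> OccurrenceMatrix:
    """Score term presence/absence over a corpus.

    ``metadata`` is a DataFrame indexed by article id with columns family,
    superfamily, descriptive; required when ``descriptive_only`` or when the
    matrix will be pruned by taxon group. Term columns are sorted
    alphabetically so corpus order affects row order only.
    """
    corpus = read_corpus(corpus)
    kinds = {TermKind(k) for k in include_kinds}
    excluded = {normalize(t) for t in exclude_terms}
    keep_labels = [
        t.label for t in lexicon if t.kind in kinds and t.label not in excluded
    ]
    if descriptive_only:
        if metadata is None:
            raise ValueError("descriptive_only requires article metadata")
        flags = metadata["descriptive"].astype(bool)
        corpus = {
            a: text
            for a, text in corpus.items()
            if a in flags.index and bool(flags.loc[a])
        }

    counts = pd.DataFrame(
        0, index=list(corpus.keys()), columns=sorted(keep_labels), dtype=np.int64
    )
    for article_id, text in corpus.items():
        match = match_terms((article_id, text), lexicon, ocr_tolerance)
        for hit in match.hits:
            label = hit.term.label
            if label in counts.columns:
                counts.loc[article_id, label] += 1

    nonzero = counts.columns[(counts.sum(axis=0) > 0).to_numpy()]
    counts = counts[list(nonzero)]
    binary = (counts > 0).astype(np.int8)
    labels = None
    if metadata is not None:
        labels = metadata.reindex(list(corpus.keys()))
    return OccurrenceMatrix(binary=binary, labels=labels, counts=counts)


def filter_by_occurrence(
    matrix: OccurrenceMatrix, k: int, mode: str = "articles"
) -> OccurrenceMatrix:
    """Keep terms by an occurrence threshold ``k``.

    ``mode='articles'`` (default): keep terms present in >= k articles.
    ``mode='occurrences'``: keep terms occurring >= k times in at least one
    article (requires raw counts). Articles are never dropped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if mode == "articles":
        keep = matrix.binary.columns[
            (matrix.binary.sum(axis=0) >= k).to_numpy()
        ]
    elif mode == "occurrences":
        if matrix.counts is None:
            raise ValueError("occurrence-count mode requires raw counts")
        keep = matrix.counts.columns[(matrix.counts.max(axis=0) >= k).to_numpy()]
    else:
        raise ValueError(f"mode must be 'articles' or 'occurrences', got {mode!r}")
    keep = list(keep)
    return OccurrenceMatrix(
        binary=matrix.binary[keep],
        labels=matrix.labels,
        counts=matrix.counts[keep] if matrix.counts is not None else None,
    )


def rank_terms(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Frequency table sorted by articles containing the term (desc), then
    total occurrences (desc), then term label (asc)."""
    n_articles = matrix.binary.sum(axis=0)
    if matrix.counts is not None:
        n_total = matrix.counts.sum(axis=0)
    else:
        n_total = n_articles
    table = pd.DataFrame(
        {
            "term": matrix.binary.columns,
            "n_articles": n_articles.to_numpy(),
            "n_total": n_total.reindex(matrix.binary.columns).to_numpy(),
        }
    )
    table = table.sort_values(
        by=["n_articles", "n_total", "term"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table
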