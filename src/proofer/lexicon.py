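"""Controlled vocabulary of anatomical and qualitative terms.

A :class:`Lexicon` holds canonical terms with their synonyms and exposes a
single flat surface-form index: every label, synonym and automatically
generated singular/plural fold maps to exactly one canonical :class:`Term`.
Lookups are O(1) on the normalized surface string, which keeps matching over
large OCR'd corpora cheap and makes the plural/synonym conflation auditable
(the index can be dumped and inspected).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "TermKind",
    "Term",
    "Lexicon",
    "LexiconCollisionError",
    "normalize",
    "plural_variants",
    "load_lexicon",
    "load_obo",
]


class TermKind(str, enum.Enum):
    """Whether a term names an anatomical structure or a quality.

    Only morphological (anatomical) terms are used as characters in the
    occurrence matrix; qualitative descriptors ('shiny', 'brown', 'rugulose')
    are recorded but excluded from analysis.
    """

    MORPHOLOGICAL = "morphological"
    QUALITATIVE = "qualitative"


class TermSource(str, enum.Enum):
    SEED = "seed"
    DISCOVERED = "discovered"


class LexiconCollisionError(ValueError):
    """Two canonical terms claim the same surface form."""


_PUNCT_STRIP = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize(surface: str) -> str:
    """Normalize a surface form: lowercase, collapse whitespace, strip
    leading/trailing punctuation (internal hyphens are kept)."""
    s = surface.lower().strip()
    s = _WS.sub(" ", s)
    return " ".join(p for p in (_PUNCT_STRIP.sub("", w) for w in s.split(" ")) if p)


# Latin singular/plural endings folded bidirectionally at index time, plus a
# plain "+s". Folding the final word only keeps multiword labels intact
# ("propleural arm" -> "propleural arms").
_LATIN_FOLDS = (("ae", "a"), ("i", "us"), ("a", "um"))


def plural_variants(form: str) -> set[str]:
    """Singular/plural variants of a normalized form (final word folded)."""
    words = form.split(" ")
    last = words[-1]
    variants: set[str] = set()

    def add(folded: str) -> None:
        variants.add(" ".join(words[:-1] + [folded]))

    add(last + "s")
    if last.endswith("s") and len(last) > 3:
        add(last[:-1])  # inverse of the "+s" fold, keeps folding an involution
    for x, y in _LATIN_FOLDS:
        if last.endswith(x) and len(last) > len(x):
            add(last[: -len(x)] + y)
        if last.endswith(y) and len(last) > len(y):
            add(last[: -len(y)] + x)
    variants.discard(form)
    return variants


@dataclass(frozen=True)
class Term:
    """One canonical vocabulary entry."""

    label: str
    synonyms: frozenset[str] = frozenset()
    kind: TermKind = TermKind.MORPHOLOGICAL
    tags: frozenset[str] = frozenset()
    source: TermSource = TermSource.SEED

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("term label must be non-empty")
        if self.label in self.synonyms:
            raise ValueError(f"label {self.label!r} repeated among its synonyms")

    def surface_forms(self) -> set[str]:
        """All explicit forms: the label and every synonym."""
        return {self.label, *self.synonyms}


class Lexicon:
    """Set of canonical terms plus the surface-form -> term index.

    Explicit forms (labels and synonyms) always win over generated plural
    folds; a generated fold claimed by two different terms is ambiguous and
    dropped from the index.
    """

    def __init__(self, terms: Iterable[Term] = ()) -> None:
        self._terms: dict[str, Term] = {}
        self._index: dict[str, Term] = {}
        self._explicit: set[str] = set()
        self.max_words: int = 1
        for t in terms:
            self.add(t)

    # -- construction -------------------------------------------------------

    def add(self, term: Term) -> Term:
        """Register a canonical term; idempotent for an identical label."""
        existing = self._terms.get(term.label)
        if existing is not None:
            return existing
        for form in sorted(term.surface_forms()):
            owner = self._index.get(form)
            if owner is not None and form in self._explicit and owner.label != term.label:
                raise LexiconCollisionError(
                    f"surface form {form!r} of term {term.label!r} already maps "
                    f"to term {owner.label!r}"
                )
        self._terms[term.label] = term
        for form in sorted(term.surface_forms()):
            self._index[form] = term  # explicit overrides any generated fold
            self._explicit.add(form)
            self.max_words = max(self.max_words, form.count(" ") + 1)
            for variant in sorted(plural_variants(form)):
                self._register_generated(variant, term)
        return term

    def _register_generated(self, form: str, term: Term) -> None:
        if form in self._explicit:
            return
        owner = self._index.get(form)
        if owner is not None and owner.label != term.label:
            del self._index[form]  # ambiguous generated fold
            return
        self._index[form] = term
        self.max_words = max(self.max_words, form.count(" ") + 1)

    def add_term(
        self,
        label: str,
        kind: TermKind = TermKind.MORPHOLOGICAL,
        tags: Iterable[str] = (),
        synonyms: Iterable[str] = (),
        source: TermSource = TermSource.DISCOVERED,
    ) -> Term:
        """Add a (reviewer-accepted) term by raw label; normalizes first."""
        label_n = normalize(label)
        if not label_n:
            raise ValueError(f"label {label!r} is empty after normalization")
        return self.add(
            Term(
                label=label_n,
                synonyms=frozenset(normalize(s) for s in synonyms if normalize(s)),
                kind=TermKind(kind),
                tags=frozenset(tags),
                source=source,
            )
        )

    # -- queries ------------------------------------------------------------

    def lookup(self, surface: str) -> Term | None:
        """Resolve a surface string to its canonical term, or None."""
        return self._index.get(normalize(surface))

    def lookup_normalized(self, form: str) -> Term | None:
        """Resolve an already-normalized form (hot path for matching)."""
        return self._index.get(form)

    def __contains__(self, surface: str) -> bool:
        return self.lookup(surface) is not None

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self._terms.values())

    @property
    def terms(self) -> tuple[Term, ...]:
        return tuple(self._terms.values())

    @property
    def index(self) -> Mapping[str, Term]:
        return dict(self._index)

    def labels(self, kinds: Iterable[TermKind] | None = None) -> list[str]:
        wanted = None if kinds is None else {TermKind(k) for k in kinds}
        return [t.label for t in self._terms.values() if wanted is None or t.kind in wanted]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the tab-separated dialect: label, synonyms, kind, tags."""
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self._terms.values(), key=lambda t: t.label):
                fh.write(
                    "\t".join(
                        (
                            term.label,
                            ",".join(sorted(term.synonyms)),
                            term.kind.value,
                            ",".join(sorted(term.tags)),
                        )
                    )
                    + "\n"
                )


def _term_from_row(row: list[str]) -> Term:
    label = normalize(row[0])
    if not label:
        raise ValueError(f"empty term label in row {row!r}")
    synonyms = frozenset(
        s for s in (normalize(x) for x in row[1].split(",")) if s and s != label
    ) if len(row) > 1 and row[1] else frozenset()
    kind = TermKind(row[2].strip()) if len(row) > 2 and row[2].strip() else TermKind.MORPHOLOGICAL
    tags = frozenset(
        t.strip() for t in row[3].split(",") if t.strip()
    ) if len(row) > 3 and row[3] else frozenset()
    return Term(label=label, synonyms=synonyms, kind=kind, tags=tags)


def load_term_list(path: str | Path) -> Lexicon:
    """Load the newline-delimited dialect (tab-separated optional columns:
    label, comma-joined synonyms, kind, comma-joined tags)."""
    lex = Lexicon()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lex.add(_term_from_row(line.split("\t")))
    return lex


_OBO_SYNONYM = re.compile(r'"([^"]*)"')


def load_obo(path: str | Path) -> Lexicon:
    """Load term names and synonyms from an OBO 1.2/1.4 flat file.

    Only [Term] stanza names and synonym strings are used; ids are kept as
    tags. No ontology semantics (relations, definitions) are interpreted.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    lex = Lexicon()
    for node_id, data in sorted(graph.nodes(data=True)):
        name = normalize(data.get("name", ""))
        if not name:
            continue
        synonyms = set()
        for raw in data.get("synonym", []):
            m = _OBO_SYNONYM.search(raw)
            if m:
                syn = normalize(m.group(1))
                if syn and syn != name:
                    synonyms.add(syn)
        lex.add(Term(label=name, synonyms=frozenset(synonyms), tags=frozenset({node_id})))
    return lex


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from an OBO file (.obo) or delimited term list."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        return load_obo(path)
    return load_term_list(path)
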