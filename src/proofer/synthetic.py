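"""Synthetic corpora with planted taxon-group structure.

Emulates the shape of a descriptive-taxonomy corpus: every article mixes
(i) ubiquitous anatomical terms found in essentially all articles, (ii)
group-specific anatomical terms shared only within a pseudo-superfamily,
(iii) qualitative filler vocabulary, and (iv) OCR character noise (the
inverse of the matcher's confusion table: l->1, o->0, m->rn, w->vv, e->e
acute). Articles are short telegraphic sentences assembling the sampled
terms with small connective words and punctuation, so segmentation,
matching, plural folding and synonym conflation are all exercised.

Everything is a deterministic function of the spec (seed included):
regenerating with the same spec is byte-identical. Group names are
pseudo-superfamilies (…oidea), each containing two pseudo-families (…idae),
so trees can be pruned at either level. Article ids interleave groups
round-robin so that lexicographic tie-breaking in clustering cannot
accidentally reconstruct the planted groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import Lexicon, Term, TermKind, plural_variants
from .occurrence import OccurrenceMatrix

__all__ = ["CorpusSpec", "SyntheticCorpus", "generate_corpus", "generate_matrix"]

# Genuine anatomy-style base vocabulary (hymenopteran flavor): Latin endings
# and hyphens exercise plural folding and tokenization edge cases.
ANATOMY_WORDS = [
    "mesoscutum", "clypeus", "tergum", "carina", "pronotum", "scutellum",
    "mandible", "flagellomere", "petiole", "gaster", "sternite", "notaulus",
    "propodeum", "mesopleuron", "metasoma", "ocellus", "antenna", "tegula",
    "axilla", "occiput", "labrum", "maxilla", "galea", "stipes", "postgena",
    "hypostoma", "epistoma", "torulus", "scapus", "pedicellus", "frons",
    "vertex-ridge", "gena", "malar-space", "tentorium", "foramen", "coxa",
    "trochanter", "femur", "tibia", "tarsus", "arolium", "pterostigma",
    "basitarsus", "spiracle", "epimeron", "episternum", "prepectus",
    "metanotum", "cenchrus", "ovipositor", "gonostylus", "volsella",
    "hypopygium", "epipygium", "cercus", "paramere", "phragma", "furcula",
    "sulcus", "fovea", "scrobe", "flange", "lamella", "condyle", "occipital-carina",
]

QUALITATIVE_WORDS = [
    "shiny", "brown", "rugulose", "smooth", "punctate", "glabrous", "dense",
    "yellowish", "darkened", "coriaceous", "striate", "reticulate", "convex",
    "concave", "elongate", "rounded", "weakly", "strongly", "sparse",
    "granulate", "polished", "dull", "pale", "blackish", "reddish",
    "flattened", "shallow", "distinct", "obscure", "slender",
]

#: Small connectives (length <= 3: removed by phrase segmentation).
SMALL_WORDS = ["the", "of", "a", "is", "in", "on", "and", "its", "at"]
#: Long connectives: phrase-eligible noise words shared across articles, the
#: raw material of the stop-word list.
LONG_WORDS = ["with", "near", "very", "both", "from", "toward", "about"]

_ONSETS = ["b", "c", "d", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z",
           "st", "pl", "tr", "cr", "br"]
_VOWELS = ["a", "e", "i", "o", "u"]
_ENDINGS = ["a", "us", "um", "is", "ella", "ium", "ula"]

_CORRUPT = {"l": "1", "o": "0", "m": "rn", "w": "vv", "e": "é"}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a planted-structure corpus.

    Defaults describe a desk-scale analogue of a descriptive-taxonomy
    journal run: a handful of superfamilies with several articles each,
    a core of ubiquitous anatomy terms, a distinct per-group vocabulary
    used in most of that group's articles, qualitative filler, and a low
    OCR character-error rate.
    """

    n_groups: int = 5
    articles_per_group: int = 8
    families_per_group: int = 2
    n_common_terms: int = 15
    n_specific_terms_per_group: int = 10
    p_specific: float = 0.9
    p_common: float = 1.0
    n_filler_words: int = 12          # filler tokens drawn per article
    ocr_error_rate: float = 0.005     # per eligible character
    p_synonym: float = 0.2            # chance a term carries a synonym
    p_plural: float = 0.25            # chance an emitted term is pluralized
    n_nondescriptive: int = 0         # extra filler-only articles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.articles_per_group < 1:
            raise ValueError("need at least one group and one article per group")
        if self.families_per_group < 1:
            raise ValueError("need at least one family per group")
        for p in (self.p_specific, self.p_common, self.ocr_error_rate,
                  self.p_synonym, self.p_plural):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticCorpus:
    """Generated articles plus all ground truth."""

    spec: CorpusSpec
    articles: dict[str, str]
    labels: pd.DataFrame               # family, superfamily, descriptive
    lexicon: Lexicon                   # morphological + qualitative truth
    groups: dict[str, str]             # article id -> superfamily
    term_groups: dict[str, str]        # specific term label -> superfamily
    term_families: dict[str, str]      # family-specific term label -> family
    common_terms: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "corpus").mkdir(parents=True, exist_ok=True)
        for article_id, text in self.articles.items():
            (out / "corpus" / f"{article_id}.txt").write_text(text, encoding="utf-8")
        lab = self.labels.copy()
        lab.insert(0, "article_id", lab.index)
        lab.to_csv(out / "labels.csv", index=False)
        self.lexicon.save(out / "truth_lexicon.tsv")
        with open(out / "truth_groups.csv", "w", encoding="utf-8") as fh:
            fh.write("article_id,superfamily\n")
            for a, g in self.groups.items():
                fh.write(f"{a},{g}\n")


def _word_factory(rng: np.random.Generator):
    """Deterministic stream of pronounceable >=4-char words, collision-free
    against everything previously issued (including plural folds)."""
    claimed: set[str] = set()

    def claim(word: str) -> bool:
        forms = {word} | plural_variants(word)
        if forms & claimed:
            return False
        claimed.add(word)
        claimed.update(forms)
        return True

    pool = list(ANATOMY_WORDS)

    def fresh() -> str:
        while pool:
            w = pool.pop(0)
            if claim(w):
                return w
        while True:
            w = (
                rng.choice(_ONSETS)
                + rng.choice(_VOWELS)
                + rng.choice(_ONSETS)
                + rng.choice(_ENDINGS)
            )
            if len(w) >= 4 and claim(w):
                return w

    return fresh, claim


def _group_names(rng: np.random.Generator, n: int) -> list[str]:
    stems = ["alph", "bet", "gamm", "delt", "epsil", "zet", "thet", "iot",
             "kapp", "lambd", "sigm", "omeg"]
    names = []
    for i in range(n):
        stem = stems[i] if i < len(stems) else "tax" + "".join(
            rng.choice(_ONSETS) for _ in range(2)
        )
        names.append(stem.capitalize() + "oidea")
    return names


def _article_ids(spec: CorpusSpec) -> list[tuple[str, int, int]]:
    """(article_id, group index, within-group index) in round-robin group
    order, so lexicographically adjacent ids belong to different groups."""
    out = []
    idx = 0
    for k in range(spec.articles_per_group):
        for g in range(spec.n_groups):
            out.append((f"a{idx:03d}", g, k))
            idx += 1
    return out


_FAMILY_SUFFIXES = ("idae", "inidae", "ulidae", "ellidae")


def _family_names(group: str, m: int) -> list[str]:
    stem = group[: -len("oidea")]
    return [
        stem.capitalize() + (_FAMILY_SUFFIXES[i] if i < len(_FAMILY_SUFFIXES)
                             else f"{i}idae")
        for i in range(m)
    ]


def _maybe_plural(rng: np.random.Generator, term: str, p: float) -> str:
    """Genuine pluralization (-um/-a, -us/-i, -a/-ae, else +s); every form
    produced here is covered by the lexicon's plural folding."""
    if rng.random() >= p:
        return term
    words = term.split(" ")
    last = words[-1]
    if last.endswith("um"):
        plural = last[:-2] + "a"
    elif last.endswith("us"):
        plural = last[:-2] + "i"
    elif last.endswith("a"):
        plural = last + "e"
    else:
        plural = last + "s"
    return " ".join(words[:-1] + [plural])


def _ocr_corrupt(rng: np.random.Generator, text: str, rate: float) -> str:
    if rate <= 0:
        return text
    out = []
    for ch in text:
        if ch in _CORRUPT and rng.random() < rate:
            out.append(_CORRUPT[ch])
        else:
            out.append(ch)
    return "".join(out)


def _build_vocab(spec: CorpusSpec, rng: np.random.Generator):
    """Disjoint vocabularies: common terms, per-group terms (split into
    group-wide and family-specific when a group has several families) and
    qualitative filler; all collision-free under plural folding."""
    fresh, claim = _word_factory(rng)
    groups = _group_names(rng, spec.n_groups)
    m = spec.families_per_group

    def make_term(kind: TermKind, tags: frozenset[str]) -> Term:
        label = fresh()
        synonyms = frozenset()
        if kind is TermKind.MORPHOLOGICAL and rng.random() < spec.p_synonym:
            synonyms = frozenset({fresh()})
        return Term(label=label, synonyms=synonyms, kind=kind, tags=tags)

    common = [
        make_term(TermKind.MORPHOLOGICAL, frozenset({"common"}))
        for _ in range(spec.n_common_terms)
    ]
    n_fam_each = spec.n_specific_terms_per_group // (2 * m) if m > 1 else 0
    n_group_wide = spec.n_specific_terms_per_group - m * n_fam_each
    group_terms: dict[str, list[Term]] = {}
    family_terms: dict[str, dict[str, list[Term]]] = {}
    for g in groups:
        group_terms[g] = [
            make_term(TermKind.MORPHOLOGICAL, frozenset({"specific", g}))
            for _ in range(n_group_wide)
        ]
        family_terms[g] = {
            fam: [
                make_term(TermKind.MORPHOLOGICAL, frozenset({"specific", g, fam}))
                for _ in range(n_fam_each)
            ]
            for fam in _family_names(g, m)
        }
    filler_pool = [w for w in QUALITATIVE_WORDS if claim(w)]
    qualitative = [
        Term(label=w, kind=TermKind.QUALITATIVE, tags=frozenset({"filler"}))
        for w in filler_pool
    ]
    lexicon = Lexicon()
    all_specific = [
        t
        for g in groups
        for t in group_terms[g] + [x for ts in family_terms[g].values() for x in ts]
    ]
    for t in common + all_specific + qualitative:
        lexicon.add(t)
    return groups, common, group_terms, family_terms, qualitative, lexicon


def _render_article(
    rng: np.random.Generator,
    spec: CorpusSpec,
    term_mentions: list[str],
    fillers: list[str],
) -> str:
    """Assemble telegraphic sentences from term surface strings."""
    mentions = list(term_mentions)
    rng.shuffle(mentions)
    fill = list(fillers)
    sentences: list[str] = []
    while mentions:
        k = int(rng.integers(1, 4))
        batch, mentions = mentions[:k], mentions[k:]
        parts: list[str] = []
        for i, m in enumerate(batch):
            small = SMALL_WORDS[int(rng.integers(len(SMALL_WORDS)))]
            parts.append(f"{small} {m}")
            if fill and rng.random() < 0.7:
                conn = LONG_WORDS[int(rng.integers(len(LONG_WORDS)))]
                parts.append(f"{conn} {fill.pop()}")
            if i < len(batch) - 1 and rng.random() < 0.5:
                parts[-1] += ","
        sentence = " ".join(parts)
        sentence = sentence[0].upper() + sentence[1:] + "."
        sentences.append(sentence)
    while fill:
        q1 = fill.pop()
        tail = f" and {fill.pop()}" if fill and rng.random() < 0.5 else ""
        sentences.append(f"Surface {q1}{tail}.")
    return " ".join(sentences)


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate articles, labels, ground-truth lexicon and group truth."""
    rng = np.random.default_rng(spec.seed)
    groups, common, group_terms, family_terms, qualitative, lexicon = _build_vocab(
        spec, rng
    )

    articles: dict[str, str] = {}
    rows = []
    group_of: dict[str, str] = {}

    for article_id, g_idx, k in _article_ids(spec):
        g = groups[g_idx]
        fam = _family_names(g, spec.families_per_group)[k % spec.families_per_group]
        mentions: list[str] = []
        for term in common:
            if rng.random() < spec.p_common:
                for _ in range(1 + int(rng.poisson(0.8))):
                    mentions.append(_emit(rng, spec, term))
        for term in group_terms[g] + family_terms[g][fam]:
            if rng.random() < spec.p_specific:
                for _ in range(1 + int(rng.poisson(0.4))):
                    mentions.append(_emit(rng, spec, term))
        fillers = [
            qualitative[int(rng.integers(len(qualitative)))].label
            for _ in range(spec.n_filler_words)
        ]
        text = _render_article(rng, spec, mentions, fillers)
        text = _ocr_corrupt(rng, text, spec.ocr_error_rate)
        articles[article_id] = text
        group_of[article_id] = g
        rows.append((article_id, fam, g, True))

    for j in range(spec.n_nondescriptive):
        article_id = f"x{j:03d}"
        fillers = [
            qualitative[int(rng.integers(len(qualitative)))].label
            for _ in range(spec.n_filler_words)
        ]
        text = _ocr_corrupt(rng, _render_article(rng, spec, [], fillers),
                            spec.ocr_error_rate)
        articles[article_id] = text
        g = groups[j % spec.n_groups]
        group_of[article_id] = g
        rows.append((article_id, _family_names(g, spec.families_per_group)[0], g, False))

    labels = pd.DataFrame(
        rows, columns=["article_id", "family", "superfamily", "descriptive"]
    ).set_index("article_id")
    labels.index.name = None

    term_groups = {
        t.label: g
        for g in groups
        for t in group_terms[g] + [x for ts in family_terms[g].values() for x in ts]
    }
    term_families = {
        t.label: fam
        for g in groups
        for fam, ts in family_terms[g].items()
        for t in ts
    }
    return SyntheticCorpus(
        spec=spec,
        articles=articles,
        labels=labels,
        lexicon=lexicon,
        groups=group_of,
        term_groups=term_groups,
        term_families=term_families,
        common_terms=[t.label for t in common],
    )


def _emit(rng: np.random.Generator, spec: CorpusSpec, term: Term) -> str:
    """Pick a surface form for one mention: synonym sometimes, plural
    sometimes."""
    surface = term.label
    if term.synonyms and rng.random() < 0.3:
        surface = sorted(term.synonyms)[0]
    return _maybe_plural(rng, surface, spec.p_plural)


def generate_matrix(spec: CorpusSpec) -> OccurrenceMatrix:
    """Planted-structure occurrence matrix without text rendering.

    Columns are the ground-truth morphological terms; common terms are
    present with probability ``p_common`` in every article, specific terms
    with probability ``p_specific`` inside their group and never outside.
    All-zero columns are dropped, mirroring matrix construction from text.
    """
    rng = np.random.default_rng(spec.seed)
    groups, common, group_terms, family_terms, _, _ = _build_vocab(spec, rng)
    ids_groups = _article_ids(spec)
    ids = [a for a, _, _ in ids_groups]

    columns = [t.label for t in common] + [
        t.label
        for g in groups
        for t in group_terms[g] + [x for ts in family_terms[g].values() for x in ts]
    ]
    data = np.zeros((len(ids), len(columns)), dtype=np.int8)
    rows = []
    for r, (article_id, g_idx, k) in enumerate(ids_groups):
        g = groups[g_idx]
        fam = _family_names(g, spec.families_per_group)[k % spec.families_per_group]
        c = 0
        for _ in common:
            data[r, c] = 1 if rng.random() < spec.p_common else 0
            c += 1
        for gg in groups:
            own_cols = [(t, None) for t in group_terms[gg]] + [
                (t, f) for f, ts in family_terms[gg].items() for t in ts
            ]
            for _, f in own_cols:
                hit = gg == g and (f is None or f == fam)
                if hit and rng.random() < spec.p_specific:
                    data[r, c] = 1
                c += 1
        rows.append((article_id, fam, g, True))

    binary = pd.DataFrame(data, index=ids, columns=columns)
    binary = binary.loc[:, binary.sum(axis=0) > 0]
    labels = pd.DataFrame(
        rows, columns=["article_id", "family", "superfamily", "descriptive"]
    ).set_index("article_id")
    labels.index.name = None
    return OccurrenceMatrix(binary=binary, labels=labels, counts=binary.astype(np.int64))
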