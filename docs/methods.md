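# Methods

This note records how `proofer` defines its procedures, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Term matching

Matching is dictionary-based by design: a curated vocabulary drives
recognition, and a human reviewer remains the authority on what enters it.
No statistical NER is attempted.

The lexicon holds canonical terms with synonyms. At load time every label
and synonym is expanded into a flat surface-form index that also contains
singular/plural folds: a plain `+s`/`−s` fold and the Latin pairs
-ae↔-a, -i↔-us, -a↔-um, applied to the final word of a form so multiword
labels fold as a unit ("propleural arm" ↔ "propleural arms"). Folding at
index time rather than stemming at query time keeps lookup O(1) and makes
the conflation auditable — the index can be dumped and inspected. Explicit
forms always win over generated folds; a generated fold claimed by two
terms is ambiguous and dropped; two *explicit* forms claiming each other is
a load-time error, never silently resolved.

Surface normalization: lowercase, collapse internal whitespace, strip
surrounding punctuation, keep internal hyphens.

Text is segmented three ways:

* **sentences** split at `.`, `!`, `?` before whitespace (no abbreviation
  list — "Fig. 3" splits; a documented limitation);
* **clauses** split sentences at punctuation (`. , ; : ( ) [ ] ! ? /` — a
  closed set, for determinism);
* **phrases** additionally split clauses at *small words* (normalized
  length ≤ 3 characters) and drop them.

Matching runs greedy longest-first over **clauses**, not phrases: at each
position the longest indexed surface form wins. This is deliberate — a
multiword anatomical label may contain a small word ("propleural arm",
"malar space of the gena"), and stripping small words before matching would
make such labels unmatchable. Phrases instead define *candidate seed
eligibility*: only uncovered words longer than 3 characters are ever
offered to the reviewer, so connectives never pollute the candidate list or
the stop-word table.

OCR tolerance is a fixed substitution table (1↔l, 0↔o, rn↔m, vv↔w, é→e)
applied as a canonical fold to both index keys and query tokens, so either
direction of a confusion matches. A deterministic table was preferred over
edit-distance search: it targets the systematic confusions of printed-text
OCR, cannot introduce seed-dependent behaviour, and its false-positive
surface is enumerable (a fold only fires when the folded token is an
indexed form).

## Candidate proposal and the stop-word loop

Every uncovered eligible word seeds one candidate per article, expanded
with 1–5 flanking words from its clause. Expansion prefers the words to the
**left** of the seed, falling back to following words when the seed sits
near the clause start. Rationale: newly discovered complex labels are
typically a known label plus a trailing head noun ("propleural arm" +
"muscle"), so completing leftward surfaces the full label among the first
expansions regardless of where the clause ends. The direction is a genuine
open choice; the opposite preference only finds such labels when the seed
ends its clause.

Rejections are tallied per word with **one vote per article**; a word
finalizes as a stop word at 10 distinct rejecting articles (configurable)
and is never proposed again. Rejecting a multiword expansion penalizes only
its seed — the flanking words may be perfectly good terms elsewhere. When a
rejection arrives as a bare phrase with no seed attached (e.g. from a
decision file), the final word is taken as the seed, consistent with the
leftward expansion rule. Accepted phrases enter the lexicon immediately
(tagged, marked as discovered) and are matchable in the very next article;
sessions checkpoint the lexicon and stop-word table after every article so
interrupted reviews resume losslessly.

## Occurrence matrices

Articles are terminals, morphological terms are binary presence/absence
characters; synonyms and plurals count toward the same canonical column.
Qualitative descriptors ("shiny", "brown") are excluded by kind, and an
explicit exclusion list (defaults: "cell", "area", "costa") removes terms
that are common outside descriptive morphology. All-zero columns are
dropped at build time: they carry no signal and break the denominators of
the asymmetric coefficients.

The occurrence-threshold filter has two modes because "occurred k times"
is genuinely ambiguous: `articles` (default) keeps terms present in ≥ k
articles; `occurrences` keeps terms occurring ≥ k times within at least one
article. The default follows the article-count reading, which produces the
nested term sets used by the threshold analyses; both ship behind a flag.

## Distances, trees, group counting

Seven coefficients form the default panel: 3 symmetric (simple matching,
Rogers–Tanimoto, Hamann-derived) and 4 asymmetric (Jaccard, Sørensen,
Ochiai, Kulczynski II); Sokal–Sneath I is also available. The panel is
configuration, not a hard-coded set. Note an algebraic coincidence: under
the (1−S)/2 normalization the Hamann-derived distance reduces exactly to
simple matching, (b+c)/n, so those two panel members always produce
identical trees; Hamann is kept as a named member for completeness but
adds no independent signal. Undefined denominators (e.g. two all-zero
articles under Jaccard) raise an explicit error naming the pair — never a
silent zero.

Linkage (single, complete, UPGMA, WPGMA) is implemented directly via
Lance–Williams updates because two conventions needed pinning that library
implementations do not expose: (1) node height = merge distance / 2, making
dendrograms ultrametric with cophenetic distance equal to merge distance,
and (2) tie-breaking — among equally close pairs, the lexicographically
smallest pair of cluster ids merges first (a cluster is named by its
smallest leaf id), so results are identical across platforms and runs. The
test suite cross-checks against `scipy.cluster.hierarchy` on tie-free
random matrices.

Neighbor-joining is the canonical Q-matrix algorithm, exact on additive
matrices (verified to 1e-9 against path-length distances of random trees,
and against `skbio.tree.nj`). Negative branch-length estimates on
non-additive input are clamped to zero with the deficit moved to the
sibling branch, preserving the pair's path length. NJ needs ≥ 3 leaves;
smaller inputs are directed to linkage. NJ trees are unrooted and are
midpoint-rooted before group counting — a rooting convention had to be
fixed, and midpoint rooting requires no outgroup knowledge.

**Group counting by trimming.** Given a tree whose leaves carry taxon
labels (family or superfamily), rounds of trimming remove every maximal
internal subtree whose leaves all share one label — each removal is one
recovered group — suppressing unary nodes between rounds, until no pure
internal subtree remains; every residual leaf then counts as its own group.
Removing a trimmed group can expose a new pure subtree (trimming a nested
foreign clade lets the surrounding same-label leaves coalesce), which is
why trimming iterates rather than collapsing once. The count is invariant
under bijective relabeling and bounded by [#labels, #leaves]. Fixed-height
tree cutting is a different statistic and is deliberately not implemented.

## Synthetic corpora

The generator emulates the structure observed in descriptive-taxonomy
corpora: a core of ubiquitous anatomical terms (present in every article by
default), group-specific vocabulary shared within a pseudo-superfamily
(each term used in a fraction `p_specific`, default 0.9, of that group's
articles and never outside), family-level vocabulary nested inside each
group, qualitative filler, small-word connectives, punctuation, Latin
plurals, synonyms, and OCR character noise applied at a per-character rate
(default 0.005) using the inverse of the matcher's confusion table.
Defaults: 5 groups × 8 articles, 2 families per group, 15 common and 10
group-specific terms per group, 12 filler tokens per article. Article ids
interleave groups round-robin so the deterministic lexicographic tie-break
in clustering cannot accidentally reconstruct the planted groups.
Generation is a pure function of the spec: the same spec is byte-identical.

What the generator does **not** model: real OCR error distributions
(segmentation noise, column breaks, ligatures), linguistic prose structure,
unbalanced group sizes, overlapping vocabularies between groups, and
homonymy across domains. Passing the planted-recovery benchmarks therefore
shows the pipeline is correct and coherent end to end — not that real
corpora of any particular journal will cluster as cleanly.

Benchmark sizes were chosen as desk-scale analogues: recovery runs 2–6
groups × 5 articles × 5 replicates through the full text pipeline; the
threshold census and Sørensen-average group count use a planted matrix of
10 superfamilies × 18 articles (180 terminals), the scale of a multi-year
journal run; the ubiquity comparison uses 4 groups × 8 articles over 10
replicates, with ubiquity meaning presence in ≥ 90% of articles.

## Known limitations

* Sentence splitting has no abbreviation handling; OCR text is taken as-is.
* The OCR confusion table is small and fixed; it recovers the listed
  systematic confusions only, not arbitrary edit errors.
* The stop-word threshold counts distinct articles globally; per-reviewer
  tallies are out of scope.
* `OccurrenceMatrix` CSV round-trips preserve presence/absence and labels
  but not raw per-article occurrence counts; total-occurrence ranking and
  the `occurrences` filter mode need the matrix built in-process.
* The trimming statistic is one reading of "pruning a tree by group"; it
  is the one whose edge cases (nested foreign clades, shuffled leaves)
  behave sensibly, but other readings (height cuts) exist.
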