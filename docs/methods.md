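# Methods

## The extraction model

`treatminer` treats drug–disease treatment extraction as seed-driven
pattern bootstrapping (distant supervision). The underlying assumption is
that although a treatment relation can be verbalized in countless ways,
authors overwhelmingly reuse a small set of stock phrasings ("DRUG in the
treatment of DISEASE", "DRUG for DISEASE"). Known treatment pairs — built
by crossing the drugs recognized in a clinical trial's intervention texts
with the diseases recognized in its condition texts — act as weak labels:
a pattern observed with many distinct known pairs is likely
treatment-specific, while patterns expressing other relations
("DRUG-induced DISEASE", an adverse effect) are observed mostly outside
the seed set. The method optimizes precision and scale rather than
recall: a handful of curated high-precision patterns applied to a large
corpus recovers most *frequently mentioned* pairs, while pairs mentioned
once or twice are structurally hard for any single-sentence pattern
matcher.

The pipeline is deliberately lexicon-bound and syntax-free: no parser, no
noun-phrase chunking, no negation handling. These are documented
limitations, not oversights (see below).

## Matching semantics

Tagging is case-insensitive exact dictionary matching with two
refinements:

* **Boundary constraint.** A match must be flanked by string edges or
  non-alphanumeric characters. "flu" never fires inside "influence";
  hyphen-adjacent mentions like "Tamoxifen-induced" are admitted because
  the hyphen is non-alphanumeric.
* **Overlap resolution.** All drug and disease candidates compete in one
  pool; selection is longest-match-first, then leftmost-first, with DRUG
  preferred on an exact same-span tie (configurable to DISEASE or
  suppression for drug/disease homonyms). Longest-first favors specific
  disease terms: in "treated breast cancer" with both "cancer" and
  "breast cancer" in the lexicon, only "breast cancer" is tagged.

The semantic contract of the matcher is the naive all-substrings scan;
the test suite enforces equivalence against an independent
implementation of that scan. Trade names are matched as surfaces but
always emitted under the generic drug name.

A pattern is the verbatim inter-mention text, case-folded, outer
whitespace trimmed, inner whitespace collapsed. Text of intervening
mentions stays inside the infix verbatim; the empty infix (adjacent
mentions) is a legal pattern but can never equal a curated non-empty one.
Pattern matching at extraction is therefore case-insensitive and
orientation-strict: a DRUG-first "in" never fires on "DISEASE in DRUG".

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| Curated pattern set | 17 DRUG-first infixes (`data/patterns_default.tsv`) | the shipped treatment-specific curation; DISEASE-first patterns are less specific and excluded |
| Sentence splitter | rule-based: `[.?!]` + space + uppercase/digit, abbreviation list, no split inside unbalanced parentheses | deterministic and reproducible; no statistical model needed at abstract scale |
| Title handling | title = sentence 0 of each document | titles carry many treatment statements ("...: a case report") |
| Section labels (`CONCLUSIONS:`) | kept (strippable via option) | labels are harmless to pattern infixes and removing them loses context |
| Homonym policy | DRUG wins a same-span tie | drug lexicons are smaller and more precise; logged whenever it fires |
| Evaluation cutoffs | 1, 5, 10, 20, 30 | the standard frequency grid for stratified recall |
| Rounding | half away from zero, 3 decimals, display only | raw ratios are retained in report objects |
| ATC comparison | full codes (level 5); optional truncation to levels 1–4 | strictest default; truncation is an explicit analysis choice |

Precision in `evaluate_at_cutoffs` is computed once on all extracted
pairs (restricted to the gold anchor) and repeated on every row: the
extracted set does not change with the cutoff, only the gold subset does.
An empty gold subset yields an undefined-recall marker, never a zero.

In the semantic analysis the drug universe is restricted to drugs that
have a disease profile (from the extracted pairs) *and* at least one gene
or ATC annotation; a drug missing from one annotation table contributes
an empty set there. This is one reading of an ambiguous restriction
("drugs appearing in both"); the alternative (separate universes per
annotation kind) changes only the all-pairs denominators.

## What the synthetic fixtures emulate

`generate_fixture` plants `<filler> DRUG <infix> DISEASE <filler>.`
sentences with controlled per-pair sentence counts (default frequency
spec: 3/3/2/2/2 pairs at counts 1/5/10/20/30, 144 sentences total), five
treatment infixes drawn from the curated set, three distractor infixes
("-induced", "-associated", "had no effect on"), a deterministic seed
subset (default fraction 0.5) emitted both as pairs and as trial records,
and optional near-miss sentences (extra words inside the infix) that
co-occur but must never be extracted. Each sentence contains exactly one
drug and one disease, so planted sentence counts *are* the co-occurrence
frequencies. Vocabulary is pronounceable nonsense with verified
collision-freedom (no term inside another term, filler or pattern), so
every tagger hit is a planted hit.

`generate_association_world` builds disease/gene/ATC tables in strata of
drug pairs with exact shared-item counts, fresh items per pair and one
private item per drug, so cross-pair sharing is zero and the expected
mean-shared-by-threshold curves follow from the stratum spec by
enumeration.

What passing on fixtures does **not** show: robustness to real-text
phenomena — abbreviations, coordination ("breast and ovarian cancer"),
lexicon gaps, term ambiguity beyond exact homonyms, discontinuous or
modified disease names ("metastatic and recurrent colorectal cancer"
when only "colorectal cancer" is in the lexicon). On real corpora these
drive precision below 1.0 and recall well below 1.0, especially for
rare pairs; the frequency-stratified evaluation exists precisely to make
that dependence visible.

## Numerical and degenerate-input choices

* Precision with an empty extracted set, and recall with an empty gold
  set, raise explicit undefined-metric errors; F1(0, 0) = 0 by
  convention.
* Pattern ranking is a total order: descending seed-pair count, then
  descending total-pair count, then ascending (orientation, infix) — so
  outputs are byte-reproducible.
* Extracted pairs are ordered by descending support, then lexicographic
  pair; all TSV writers sort, so identical inputs give identical bytes.
* Case folding of sentence text is length-preserving (fallback chain
  casefold → lower → per-character) so mention offsets always index the
  original sentence string.
* A citation without an identifier is skipped with a warning rather than
  failing the whole file; a trial record without an identifier is an
  error since seeds are keyed by trial.

## Problem sizes

The default test and analysis corpora are 144–160 sentences with 8-drug /
8-disease vocabularies, 24-drug association worlds, and 200-sentence
oracle-equivalence samples. These sizes fully exercise every code path
(multi-frequency strata, trade names, distractors, near-misses) while the
whole suite runs in seconds; the algorithms are linear in sentences ×
lexicon surfaces and stream sentence-by-sentence, so corpus scale is an
I/O concern, not an algorithmic one.

## Known limitations

* Single-sentence, single-pattern extraction: relations expressed across
  sentences or outside the two-mention infix are invisible, and context
  around the pair ("treat DISEASE with DRUG") is ignored by design.
* Dictionary recall is bounded by the lexicons; no fuzzy or
  abbreviation-aware matching.
* No negation or outcome polarity: "was not effective in the treatment
  of" still matches "in the treatment of". Extracted pairs mean "was
  discussed as a treatment", not "is an effective treatment".
* The pure-Python matcher scans every lexicon surface per sentence; for
  corpora of millions of sentences an automaton (Aho–Corasick) drop-in
  would be the natural optimization — by contract it must reproduce the
  naive-scan semantics exactly.
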