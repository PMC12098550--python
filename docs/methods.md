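# Methods

This note documents the models, parameter choices and known limits of
the `sdmstylo` pipeline: the tokenization and metric definitions, the
stylometric classification procedure, the synthetic corpus generator
that stands in for clinical transcripts, and the numerical conventions
used throughout.

## Study design and data model

The pipeline targets a two-group design: two cohorts of 24 participants
each, every participant contributing three self-defining memories
(SDMs), i.e. 72 documents per group and 144 in total. Two participants
per group are flagged *held out*: their texts never enter the per-group
training streams and form a participant-blind test set. A "study-design
mode" validation switch enforces the 3-documents-per-participant shape;
with it off, ragged corpora are accepted (real collections lose
documents).

Per-group streams concatenate documents in (participant id, index)
lexicographic order. The order is a convention — nothing downstream
depends on which one is chosen, but chunk boundaries must be
reproducible across runs, so one fixed order is required.

## Tokenization and annotation

Delimiters are whitespace, punctuation, apostrophes and hyphens.
Punctuation marks are emitted as tokens; an apostrophe terminates the
token it follows and stays attached to it (`J'ai` → `J'` + `ai`,
matching Universal Dependencies clitic segmentation for French — the
split point is a convention, the count of 2 is the requirement); a
hyphen flanked by word characters is a silent delimiter (`beau-père` →
`beau` + `père`, the hyphen is not a token), while a free-standing dash
is an ordinary punctuation token. Token spans index into the source
string, so tokenization is lossless and reconstructible.

Case folding for type comparison preserves diacritics (`à` ≠ `a` —
French function words are diacritic-sensitive). POS tags use the 17-tag
Universal POS inventory. The bundled tagger is a deterministic
lowercase lexicon lookup with punctuation detected by character class
and unknowns tagged `X`; it exists so the synthetic corpus (whose
emission lexicon it shares) is fully taggable offline. Real corpora
should arrive with CoNLL-U from a statistical annotator such as UDPipe;
the reader consumes only FORM and UPOS and expands multiword-token
ranges into their syntactic words, so `j'ai` contributes two tokens on
both paths. Both annotation paths produce identical metric values given
identical token/UPOS sequences (tested).

## Metrics

- **Wordcount** includes punctuation tokens by default, because the
  token definition counts "words, punctuation marks and/or symbols";
  an `include_punct` switch exposes the alternative.
- **MATTR** uses window W = 50 and *excludes* punctuation by default
  (a repeated comma would read as lexical repetition). For documents
  shorter than the window — plausible here, with clinical-group means
  near 72 tokens and SD above 30 — the plain whole-text TTR is the
  documented fallback. The implementation is an O(N) sliding count,
  verified exactly (1e-12) against a materialize-every-window oracle.
- **ALD** segments the text into consecutive 50-token segments (the
  MATTR window length, adopted because no independent segment length
  presents itself), keeps the final partial segment, computes
  100·content/tokens per segment with content = {NOUN, VERB, ADJ,
  ADV} (auxiliaries are *not* content), and averages unweighted.
  Punctuation stays in the denominator, consistent with the wordcount
  token definition.
- **Cohesion score** counts tokens tagged {PRON, ADV, DET, CCONJ}
  across a participant's pooled narratives. The default is the **raw
  count**: a per-category-mean normalization would land near 1,
  incompatible with reported group means in the 60–100 range, which
  are consistent with raw counts at these document lengths. The
  normalized variant (devices / total tokens) is available behind
  `normalize=True` for length-corrected analyses.
- **Group comparison** is a two-sided Wilcoxon rank-sum test (exact
  null for combined n ≤ 20 without ties, tie-corrected normal
  approximation otherwise), reporting the rank-sum W of the first
  group. Means/SDs are document-level for wordcount, MATTR and ALD and
  participant-level for CS, following the metric's unit of definition.

## Features and normalization

Chunks are consecutive non-overlapping n-token spans of a group
stream; a trailing remainder shorter than n/2 is discarded, otherwise
kept as a short sample (a convention — silently merging it would make
one sample double-length, discarding everything wastes up to half a
chunk). Chunk length counts all tokens including punctuation; a switch
exposes the word-only interpretation.

Function-word features are relative frequencies over the sample's
non-punctuation tokens, against a bundled ~130-entry French lexicon
(articles, prepositions, pronouns, conjunctions, auxiliary forms,
high-frequency adverbs, clitics with their apostrophe). The lexicon is
a plain text file and fully user-replaceable.

Character 3-gram features rebuild the sample as lowercased forms
joined by `_` and count all contiguous 3-character substrings; grams
cross token boundaries through the space marker. The feature space is
the union of grams observed on the data the matrix is built from; when
a vocabulary is imposed (evaluating held-out text against a trained
model), out-of-vocabulary grams are ignored rather than added.

Normalization is per-feature z-scoring (population SD, so fitted
columns have exactly unit SD) followed by per-row L2 normalization.
Statistics are estimated on the fitting subset only and carried with
the matrix/model for held-out application; zero-variance features are
scaled to 0 with a warning but kept, so feature indices stay stable;
all-zero rows keep norm 0.

## Classification

The classifier is `SVC(kernel="linear")` — exact hinge-loss
maximum-margin — with C = 1.0 by default (configurable; no evidence
for another value). Class weights may be explicit, "balanced"
(inversely proportional to class frequencies), or absent. Resampling
applies to training rows only: seeded uniform undersampling of the
majority class, seeded with-replacement oversampling of the minority,
or Tomek-link removal (mutual Euclidean nearest neighbors of opposite
class; only the majority member of each link is dropped, the standard
boundary-cleaning practice). When training classes are already
balanced, under/oversampling is the identity. Note the convention:
*undersample the majority, oversample the minority* — the standard
semantics.

Cross-validation is stratified k-fold (k = 10 by default) with
normalization, resampling and the model all fitted strictly inside the
training folds. At this corpus scale a group stream of roughly 5–7.5
thousand tokens yields only ~5–7 chunks per class, fewer than k; the
splitter therefore distributes each class as evenly as possible across
folds (fold sizes differ by at most one) and allows folds that contain
a single class — the training side always retains both. This mirrors
the original design's arithmetic, where 10 folds were applied to
corpora of comparable size. The pooled confusion matrix over all folds
is the headline estimate.

Evaluation computes the 2×2 confusion matrix (rows = actual) and, per
class, precision TP/(TP+FP), recall TP/(TP+FN), F1 =
2PR/(P+R), support, plus overall accuracy = trace/total; reports
round to 2 decimals. The blind test evaluates held-out participants'
text, chunked at the same n and projected into the trained model's
feature space with its stored scaling. With only 2 participants per
group held out (roughly 450–650 tokens per group), large chunk sizes
can leave a group with no blind sample — the report then simply shows
support 0 for it; the pipeline reports whatever supports its split
produces rather than forcing a particular table shape.

Markers are features ranked by signed hyperplane weight: most negative
→ pulling toward the alphabetically first class, most positive →
the second; ties break alphabetically and zero weights never rank.

The grid runner selects its "best" configuration by minority-class F1
rather than accuracy: in a screening context a missed case costs more
than a false alarm.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis consumes
— lengths, POS composition, marker-word rates, local type diversity —
and nothing else: no syntax, no semantics, no discourse. Tokens are
drawn independently; each word position falls into one of four
emission classes (marker / cohesive device / content / filler), and a
sentence-final `.` is emitted after every 12 words. Content forms are
Zipf-distributed pseudo-lemmas (syllable-composed, tagged
NOUN/VERB/ADJ cyclically); devices and fillers come from small fixed
French function-word sublexicons. Every emitted token carries a gold
UPOS tag, and the emission lexicon is closed: retagging generated text
with the bundled tagger reproduces the gold annotation with zero `X`
tags (tested).

Default profiles (the study conditions):

| parameter | clinical (ADHD) | control | rationale |
|---|---|---|---|
| participants × docs | 24 × 3 | 24 × 3 | study design |
| length mean ± SD (tokens, lognormal) | 71.667 ± 32.493 | 104.069 ± 41.279 | reported group means/SDs |
| content vocabulary / Zipf exponent | 250 / 1.25 | 600 / 1.00 | lower local diversity (MATTR) for the clinical group |
| cohesive-device rate (per word) | 0.19 | 0.21 | with marker contributions, raw CS lands near the reported ≈67 vs ≈97 |
| content rate (per word) | 0.33 | 0.35 | slightly lower density for the clinical group |
| elevated markers | "on" .030, "et" .035, "donc" .012, "avec" .012 | "je" .035, "des" .020, "me" .015, "plus" .012 | directions of the reported marker rankings |

Lengths are truncated at 20 tokens so the MATTR short-text fallback is
exercised deliberately by stress configurations rather than by the
default corpus. Probability budgets are validated (≤ 1) before
emission; the filler class absorbs the remainder.

Because device words include ADV forms, cohesion and density are
weakly coupled (ADV is both a cohesive device and a content tag); the
content sublexicon therefore avoids ADV so the device rate remains the
primary cohesion dial.

**What passing tests show — and don't.** The synthetic corpora make the
planted contrasts recoverable end-to-end: pooled cross-validated
accuracy above 0.9, "on"/"je" in the top-3 markers of their sides in
≥9/10 seeds, and >90% power at p < 0.005 for the wordcount comparison
at 24+24. Because tokens are drawn independently with group-constant
rates, these corpora are *easier* than real narratives (no topic
variation, no within-group heterogeneity, no annotation noise);
passing therefore validates the pipeline's correctness and wiring, not
the clinical effect size or the transportability of any particular
accuracy figure to real transcripts.

## Problem sizes and determinism

Default analyses run at the study scale (144 documents, ~13k tokens
per corpus; chunk size 1000 for cross-validation, giving ~12 samples);
the acceptance script averages classifier metrics over 10 seeded
corpora and measures wordcount power over 100 replicates. Every source
of randomness (corpus generation, fold shuffling, resampling, SVM
seed) derives from a single integer seed; identical configuration and
seed reproduce byte-identical artifacts, and each run writes a
manifest (config hash, seed, version, counts) sufficient to reproduce
it.

## Known limitations

- The bundled tagger is lookup-only; real French text needs external
  CoNLL-U annotation, and tagger errors propagate directly into ALD
  and CS.
- Chunk sizes of 1000+ tokens against ~5–7k-token group streams leave
  very few samples; fold-level metrics are coarse and the pooled
  confusion is the only stable summary. Blind-test supports can be 0
  for a group at large n.
- The linear-SVM marker ranking reads magnitude of signed weights;
  with correlated features (3-grams of one word) weight mass spreads,
  so marker lists are indicative, not effect-size estimates.
- Wilcoxon p-values for document-level metrics treat documents as
  independent, ignoring the participant clustering (three documents
  per writer); participant-level aggregation (as for CS) is the
  conservative alternative.
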