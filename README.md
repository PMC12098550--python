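# sdmstylo

Stylometric analysis of **self-defining memory (SDM) narratives** for
two-group clinical comparison — e.g. adolescents with ADHD vs. typically
developing peers. SDMs are short autobiographical texts elicited with a
standardized task (three per participant); subtle differences in *how*
they are written (not what they are about) carry a group-level signal
that content-independent stylometric features can pick up.

The package is aimed at researchers in clinical computational
linguistics / digital phenotyping who want a reproducible, tested
pipeline for this design, plus a seeded synthetic-corpus generator so
every stage can be exercised without access to clinical transcripts.

## What it computes

**Linguistic metrics** (per document or participant, compared between
groups with a two-sided Wilcoxon rank-sum test):

- *Wordcount* — token count after tokenization in which whitespace,
  punctuation, apostrophes and intra-word hyphens are delimiters
  (`J'ai` = 2 tokens, `beau-père` = 2 tokens; punctuation marks count
  as tokens).
- *MATTR* — moving-average type-token ratio: the mean of
  `V_i / W` over all sliding windows of `W = 50` tokens, where `V_i`
  is the number of distinct types in window *i*; a length-independent
  lexical-diversity estimate.
- *ALD* — average lexical density: the text is cut into consecutive
  50-token segments and `100 · #content / #tokens` (content = NOUN,
  VERB, ADJ, ADV) is averaged over segments.
- *Cohesion score (CS)* — participant-level count of cohesive-device
  tokens (PRON, ADV, DET, CCONJ) pooled over the participant's three
  narratives.

**Stylometric classification.** Per-group text streams (with 2 + 2
held-out participants excluded for a blind test) are chunked into
*n*-token samples (n ∈ {1000, 1250, 1500, 1750, 2000}); features are
function-word relative frequencies or character 3-gram relative
frequencies (spaces marked `_`, so `ng_` is a word-final gram);
columns are z-scored with statistics from the training folds only,
rows L2-normalized; a linear SVM (hinge loss, C = 1) is trained with
optional class weights and resampling (random under/oversampling or
Tomek-link removal) under stratified 10-fold cross-validation.
Evaluation reports per-class precision, recall, F1 and support plus
accuracy; the signed hyperplane weights rank the function words or
3-grams that pull toward each group ("markers").

## Worked example

```python
import numpy as np
from sdmstylo import (
    default_config, generate, chunk, fw_matrix, normalize,
    cross_validate, train, top_markers, wordcount, compare_groups,
)

corpus, ann = generate(default_config(seed=1))   # 2 groups x 24 x 3 SDMs
samples = []
for group in ("ADHD", "control"):
    pids = [p.id for p in corpus.group_participants(group)]
    tokens = [t for pid in pids for d in corpus.documents_of(pid)
              for t in ann[(pid, d.index)].tokens]
    samples += chunk(tokens, 1000, group=group)

matrix = fw_matrix(samples)
_, pooled = cross_validate(matrix, k=10, class_weights="balanced", seed=1)
print(f"pooled CV accuracy: {pooled.accuracy:.2f}")

model = train(normalize(matrix), class_weights="balanced", seed=1)
neg, pos = top_markers(model, k=3)
print("ADHD-side markers:   ", [n for n, _ in neg])
print("control-side markers:", [n for n, _ in pos])

wc = {g: [wordcount(ann[(p.id, d.index)])
          for p in corpus.group_participants(g)
          for d in corpus.documents_of(p.id)] for g in ("ADHD", "control")}
comp = compare_groups(wc, metric="wordcount")
print(f"wordcount means: {comp.group_means[0]:.1f} vs {comp.group_means[1]:.1f}, "
      f"p = {comp.p_value:.2e}")
```

Output:

```
pooled CV accuracy: 1.00
ADHD-side markers:    ['on', 'et', 'avec']
control-side markers: ['je', 'plus', 'des']
wordcount means: 71.8 vs 98.5, p = 2.14e-06
```

The classifier separates the two synthetic groups perfectly at this
seed; the marker lists recover the planted contrasts (the collective
pronoun "on" and syntactic connectives on the clinical side, the
first-person "je" on the control side); and the clinical group's
narratives are significantly shorter.

The same pipeline is available from the shell:

```bash
sdmstylo run --source synthetic:default --chunk-size 1500 \
    --feature-family fw --class-weights balanced --resampling tomek_links \
    --seed 1 --out runs/demo
sdmstylo grid --chunk-sizes 1000,1500 --feature-families fw,char3 \
    --class-weights balanced --seed 1 --out runs/grid
```

Real corpora are supplied as a directory with `metadata.tsv`
(columns `id`, `group`, `heldout`, optional `age`, `sex`), one UTF-8
text file `texts/<id>_<k>.txt` per narrative, and optional CoNLL-U
annotations under `conllu/` from any external POS annotator (only the
FORM and UPOS columns are used).

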