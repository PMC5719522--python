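# gprelex

Genotype–phenotype relationship extraction from annotated biomedical
sentences.

Statements like *"The association of IBD5 with ulcerative colitis is
confirmed"* carry the experimental findings that genotype–phenotype databases
are built from, but they are locked inside free text. `gprelex` implements a
complete, self-contained pipeline for deciding, for every (genotype mention,
phenotype mention) pair inside a sentence, whether the sentence asserts a
relationship between them. It is aimed at biomedical text-mining researchers
who want a reproducible, corpus-free reference implementation of the classic
rule + maximum-entropy + self-training recipe for this task.

## What is inside

* **Rule-based extractor** (`gprelex.rule_extractor`) — five linguistic
  patterns over a relationship-term lexicon REL and the closed preposition set
  PREP = {of, by, to, on, for, in, through, with}:
  `E1 REL E2`; `E1 REL PREP+ E2`; relation chained through a REL nominal on
  the dependency path; `REL (PREP|between) E1 and E2`; and slash-joined pairs
  `E1/E2` with a nearby REL. Negated statements ("no correlation …") are
  deliberately still matched positive, reproducing the known failure mode of
  general-purpose relation tools (an opt-in `--veto-neg` flag suppresses
  them).
* **Feature extractor** (`gprelex.feature_extraction`) — sparse binary
  features per candidate pair: the relationship term at the dependency-path
  root with stem/position/grammatical role; the *key term* chosen by a
  four-step precedence procedure over linear position and dependency
  dominance; two collapsed versions of the dependency path
  (`nsubj|nsubjpass → subj`, `rcmod|partmod → mod`, `prep_x → x`, else `O`;
  and prep-only); negation-dominance and double-`prep_between` indicators;
  constituency LCA-head and label×distance path features; and lexicon terms
  in a 4-token surface window.
* **Maximum-entropy classifier** (`gprelex.maxent_classifier`) — count-based
  feature selection and an L2-regularized logistic model over the indicators,
  with calibrated posteriors `p(rel | x) = σ(wᵀx + b)` and bit-reproducible
  JSON serialization.
* **Self-training loop** (`gprelex.selftrain`) — agreement-based seed
  bootstrapping (keep sentences where the rule and model systems agree on at
  least one positive), then iterative promotion of unlabelled instances whose
  confidence lies in the interval `[α, β] = [0.85, 0.92]`, at most 15 per
  iteration, requiring rule agreement during the first 5 of 6 iterations.
  Promoting only mid-confidence instances avoids the overfitting that
  top-confidence promotion causes.
* **Synthetic corpus generator** (`gprelex.synthetic_corpus`) — hand-authored
  templates with gold labels, dependency trees (collapsed Stanford dialect),
  and Penn-style constituency trees, covering the five positive patterns plus
  negation, aim-statement, and distractor sentences at a ~2:1
  positive:negative instance ratio. Everything is reproducible from a seed;
  no parser or download is needed anywhere in the test suite.
* **Evaluation** (`gprelex.evaluation`) — instance-level precision, recall,
  and F-measure (harmonic mean), on the 0–100 scale.

## Worked example

```bash
gprelex generate --n 300 --seed 7 --out corpus.jsonl
gprelex featurize --corpus corpus.jsonl --out instances.jsonl
gprelex train --instances instances.jsonl --out model.json
gprelex predict --model model.json --instances instances.jsonl --out preds.jsonl
gprelex evaluate --pred preds.jsonl --gold corpus.jsonl --out metrics.json
```

prints

```
{"tp": 191, "fp": 0, "fn": 0, "tn": 109, "precision": 100.0, "recall": 100.0, "f_measure": 100.0}
```

i.e. on its own 300-sentence training corpus (191 positive and 109 negative
candidate pairs) the classifier separates relations from negations, aim
statements, and distractors perfectly. The held-out benchmark is harder:

```bash
gprelex run-supervised --seed 7 --out sup.json
# {"tp": 124, "fp": 0, "fn": 7, "tn": 69, "precision": 100.0, "recall": 94.66, "f_measure": 97.25}

gprelex run-selftrain --n-train 500 --n-test 200 --seed 7 --out selftrain.json
# {"selftrain": {... "f_measure": 100.0}, "seed_supervised": {... "f_measure": 100.0}, "instances_added": 45}
```

`run-supervised` trains on 500 generated sentences and evaluates on 200
unseen ones. `run-selftrain` keeps only a 10% labelled seed, treats the rest
as an unlabelled pool, and runs the interval-gated loop; here it promoted 45
pool instances over 6 iterations without degrading the seed baseline.

In the library, the classic worked example is one call away:

```python
>>> from gprelex import dependency_path
>>> from gprelex.synthetic_corpus import worked_example
>>> s = worked_example()   # "The association of Genotype1 with Phenotype2 is confirmed."
>>> dependency_path(s.deps, 3, 5).to_string(s.surfaces)
'Genotype1-prep_of-association-prep_with-Phenotype2'
```

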