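# Methods

## Task and representation

The unit of prediction is the *instance*: one (genotype mention, phenotype
mention) ordered pair inside a single sentence, labelled positive when the
sentence asserts a relationship between the two entities. Pairing is strictly
intra-sentential, and duplicate entity strings at different token offsets are
distinct instances. Sentences carry token-offset entity spans (exportable as
IOB tags), a dependency tree in the collapsed-preposition Stanford label
dialect, and optionally a Penn-style constituency tree. Because collapsed
output absorbs preposition tokens into edge labels (`prep_of`, `prep_with`),
fixture trees re-attach the absorbed function words (`case`/`cc` edges) so
every tree remains a single-rooted spanning tree; these bookkeeping edges
collapse to the placeholder in the path features and are invisible to the
model.

A multi-token mention is anchored in the dependency tree by a single head
token, by default the last token of the span (biomedical noun phrases are
typically right-headed); corpus files may override the head explicitly. This
anchoring is a modelling choice, not a property of the data, and is the main
knob to vary in sensitivity analyses.

## Rule-based extractor

Five surface/dependency patterns over a relationship-term lexicon (about 50
surface forms covering verbs such as *cause*, *associate*, *confer*, their
nominalizations, and the relational prepositions *in* and *for*; lookup is
case-insensitive and stem-based, so inflections collapse). P1/P2/P4/P5 are
token-sequence matchers around the mention pair; P3 is matched on the
dependency path: every interior node must be a relationship term or a noun,
at least one interior node must be a relationship term, at least one edge
must be `prep_x` with `x` in the closed preposition set, and the chain is
capped at 6 edges. `prep_between` chains are excluded from P3 so that
"REL between X and Y" coordinations are attributed to P4. A pair is reported
at most once; the first matching pattern in the order P1→P5 wins, which makes
match lists deterministic.

Negation is *not* vetoed by default: "no correlation … was found" matches
positively, as general-purpose relation extractors of this family do. The
classifier, not the rules, is responsible for negation, via the
negation-dominance feature. `veto_neg` suppresses matches whose entity path
dominates a `neg` edge, for callers who want a higher-precision rule system.

## Feature extraction

Nine feature families, all binary indicators (a bag of named instantiations,
the natural encoding for a maximum-entropy model):

| family | content |
|---|---|
| `relterm` | path-root relationship term, stem, relative position, grammatical role |
| `keyterm` | four-step key term and its relative position |
| `collapsed1` | fully collapsed dependency path |
| `collapsed2` | prep-only collapsed dependency path |
| `neg` | some path node dominates a `neg` edge |
| `dblbetween` | two consecutive `prep_between` path edges |
| `synlca` | stem of the constituency LCA head if it is a relationship term, else NULL |
| `synpath` | constituent label × distance chains from the LCA to each entity |
| `surf` | lexicon terms between the mentions or within 4 tokens outside them |

Conventions that the data did not fix and we chose once:

* **Stemming.** A self-contained Porter (1980) stemmer, applied uniformly to
  lexicon and text. The single-pass algorithm is not idempotent
  ("causes" → "caus" → "cau"), so the pass is iterated to a fixed point;
  the stem is an internal key, never a displayed form, so the extra
  truncation is harmless and buys `stem(stem(w)) == stem(w)`.
* **Relative position** (`before`/`between`/`after`) is defined by the linear
  order of the two mentions, not by entity type. All path-content features
  are computed on the linearly-first→second path and are therefore invariant
  under swapping which mention is the genotype; the single role-encoding
  feature (`relterm:dep`, the path edge labels on the genotype and phenotype
  sides of the path root) is etype-anchored on purpose — it is what lets the
  model tell "PHENO is associated with GENO" from an aim statement in which
  the genotype is the grammatical subject.
* **Key term.** Step 1: a relationship term linearly between the mentions
  that dominates both entity heads (dominance is ancestor-or-self, so a
  copular root can qualify). Step 2: a dominating word between the mentions
  with a relationship-term dependency child — that child wins. Steps 3 and 4:
  the same two checks outside the mention pair. Earlier steps win; within a
  step, the candidate closest to the midpoint of the pair wins, ties breaking
  leftward. The tie-break is our addition (the procedure is silent on
  multiple qualifying terms) and is exercised against an exhaustive oracle in
  the tests. Elsewhere `dominates` is proper (a node does not dominate
  itself).
* **Surface window.** "Within 4 tokens" is inclusive of the 4th token.
* **Missing constituency tree** yields only a `synlca:noctree` flag; when the
  path root is not a lexicon term the `relterm`/`keyterm` families emit a
  NONE sentinel rather than disappearing, so vector shape is stable.
* **Collins-style head table** for {S, SBAR, VP, NP, PP, ADJP, ADVP} only;
  fixture trees can pin a head child explicitly, which overrides the table.
  Full head-percolation tables are unnecessary at fixture scale.

## Classifier

Binary logistic regression (the binary maximum-entropy model) over the
selected features, fit with scikit-learn's deterministic LBFGS. Feature
selection keeps features occurring in at least `min_count = 2` training
instances. The objective is the **mean** log-loss plus `(λ/2)‖w‖²`, so the
fitted decision function is exactly invariant under duplicating the training
set (the library's `C` is set to `1/(nλ)`). The default `λ = 0.01` is the
conventional weak ridge prior for sparse binary indicators — it corresponds
to `C = 1` at n = 100 — and matters: at `λ = 1` the prior overwhelms the
indicators and the model collapses to the majority class under the 2:1
positive skew. Class imbalance is otherwise left uncorrected by default
(the remedy modelled here is adding negative sentences to the data, not
reweighting); an optional balanced class-weight flag exists. Confidence is
the posterior of the predicted class, in [0.5, 1]. Models serialize to
portable JSON (feature names + weights), and prediction recomputes the
logistic from the stored weights, so a save/load round trip reproduces
predictions bit-identically.

## Seed bootstrapping and self-training

`agreement_bootstrap` emulates semi-automatic corpus construction: every
candidate pair is labelled independently by the rule system and a model;
instances with agreeing labels are kept, a sentence is retained when it has
at least one agreed positive, and sentences with any disagreement are routed
to an audit list (in the original workflow these become human-annotation
candidates for the test set).

The self-training loop starts from a labelled seed and an unlabelled pool of
featurized instances. Per iteration: train → predict the pool → promote at
most `cap` instances whose confidence lies in the **inclusive** interval
`[α, β]` — ranked by confidence descending, instance key as tie-break —
moving them to the labelled set with their predicted (and thereafter frozen)
labels. During the first `rule_iters` iterations a promotion additionally
requires the predicted label to equal the rule label, for both classes. The
upper bound β exists because promoting the most confident instances feeds the
model its own certainties and overfits; the band selects instances the model
is sure enough about to trust but still learns from. Defaults are the best
configuration of the original study: `α = 0.85`, `β = 0.92`, `cap = 15`,
`rule_iters = 5`, `max_iters = 6`, hence at most 90 promoted instances.
The textual description of the band is strict ("more than α, less than β");
we make both ends inclusive so the round printed bounds are attainable.
The loop always runs `max_iters` iterations — an iteration may promote
nothing — so an empty pool reduces exactly to supervised training, and the
per-iteration trace (interval-gated count, rule-surviving count, promotions
with confidences, labelled-set size, optional held-out metrics) always has
`max_iters` records. `grid_run` repeats the loop over a configuration grid
and serializes per-iteration precision/recall/F trajectories.

## Synthetic benchmark

The generator instantiates 13 hand-authored templates: the five positive
patterns (with lexical variation in the relation word), two negation
templates (including one modelled on the "no correlation in patients …"
construction, with a `neg` edge on the relation nominal), one aim-statement
template ("The present study was undertaken to investigate whether …",
gold-negative although every rule system calls it positive), and three
distractor templates containing both entity types but no relation trigger.
Entity fillers are synthetic identifiers (`GENO_0042`), so fixtures encode no
real biomedical claims. Default category mix: negation 0.10, aim 0.08,
distractor 0.15, the rest positive — roughly the 2:1 positive:negative
instance skew of hand-built training sets for this task. Label noise is off
by default. Benchmarks use 500 training and 200 test sentences, split at the
sentence level before pair expansion (no sentence leaks across the split);
self-training benchmarks keep a 10% sentence-level labelled seed. Three-seed
medians are reported. The whole benchmark runs in seconds, so no scaling
down was needed anywhere.

What the benchmark does *not* show: real abstracts have parser errors,
anaphora, ellipsis, generic referring expressions, sub-cellular phenotypes
with reversed causal direction, and far more lexical and syntactic variety
than 13 templates. Near-perfect synthetic scores validate the machinery —
feature wiring, gating logic, determinism — not performance on PubMed text;
on real corpora this family of methods sits near F ≈ 0.78, not F ≈ 0.97.
Templates are authored, not parsed, which is why the suite needs no parser;
the CoNLL-U reader exists for users who bring their own parses.

## Determinism and degenerate inputs

Every stochastic component takes an explicit seed, and equal seeds give
byte-identical corpora, models, and traces. Degenerate metric ratios (0/0)
are reported as 0 with a warning. Dependency-path extraction rejects
identical endpoints; tree validation distinguishes multi-headed tokens,
cycles, and forests. Candidate selection with `max_iters = 0` returns the
supervised model untouched.

## Known limitations

* The rule patterns are the five documented schemata, not a full RelEx rule
  set; P3's 6-edge cap is a configuration choice.
* The bundled lexicon is a compact reconstruction (~50 surface forms), not
  the original ~270-word / 808-surface-form list, which is not distributed
  with this package.
* The exact stemmer and maxent hyperparameters of the original Mallet-based
  system are unknown; Porter and the defaults above are declared stand-ins.
* Whether the per-iteration cap counts instances or sentences is ambiguous in
  the source description; it is read here as instances.
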