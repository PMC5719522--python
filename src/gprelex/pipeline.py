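"""End-to-end orchestration: featurize, split, train, self-train, evaluate.

Train/test splitting is by a stable hash of the sentence id, before pair
expansion, so no sentence contributes instances to both sides.
"""

from __future__ import annotations

import hashlib
import random
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from gprelex.corpus_io import (
    AnnotatedSentence,
    Lexicon,
    RelationInstance,
    candidate_pairs,
    default_lexicon,
)
from gprelex.evaluation import Metrics, score
from gprelex.feature_extraction import extract_features
from gprelex.maxent_classifier import TrainConfig, TrainedModel, predict, train
from gprelex.rule_extractor import rule_labels_for_corpus
from gprelex.selftrain import (
    LabelledInstance,
    SelfTrainConfig,
    SelfTrainTrace,
    self_train,
)
from gprelex.synthetic_corpus import GeneratorConfig, generate_corpus


def split_by_sentence(
    corpus: Sequence[AnnotatedSentence], train_frac: float = 0.7
) -> tuple[list[AnnotatedSentence], list[AnnotatedSentence]]:
    """Deterministic sentence-level split by id hash; no sentence leaks."""
    train_set, test_set = [], []
    for sent in corpus:
        digest = hashlib.md5(sent.id.encode("utf-8")).digest()
        bucket = int.from_bytes(digest[:4], "big") % 1000
        (train_set if bucket < train_frac * 1000 else test_set).append(sent)
    return train_set, test_set


def featurize_corpus(
    corpus: Sequence[AnnotatedSentence], lexicon: Lexicon
) -> list[LabelledInstance]:
    """Labelled feature vectors for every candidate pair.

    A pair with no gold relation record is a negative instance; gold labels
    override.
    """
    out = []
    for sent in corpus:
        gold = {r.key: r.label for r in sent.gold_relations}
        for cand in candidate_pairs(sent):
            out.append(
                LabelledInstance(
                    key=cand.key,
                    features=extract_features(sent, cand, lexicon),
                    label=gold.get(cand.key, "negative"),
                )
            )
    return out


def gold_instances(corpus: Sequence[AnnotatedSentence]) -> list[RelationInstance]:
    out = []
    for sent in corpus:
        gold = {r.key: r for r in sent.gold_relations}
        for cand in candidate_pairs(sent):
            rel = gold.get(cand.key)
            if rel is None:
                rel = RelationInstance(*cand.key, label="negative", provenance="gold")
            out.append(rel)
    return out


def predict_instances(
    model: TrainedModel, instances: Sequence[LabelledInstance]
) -> list[RelationInstance]:
    out = []
    for inst in instances:
        pred = predict(model, inst.features)
        out.append(
            RelationInstance(
                *inst.key, label=pred.label,
                confidence=pred.confidence, provenance="model",
            )
        )
    return out


def evaluate_model(
    model: TrainedModel, instances: Sequence[LabelledInstance]
) -> Metrics:
    predicted = predict_instances(model, instances)
    gold = [RelationInstance(*i.key, label=i.label) for i in instances]
    return score(predicted, gold)


# ---------------------------------------------------------------------------
# benchmark runs
# ---------------------------------------------------------------------------


@dataclass
class SupervisedResult:
    model: TrainedModel
    metrics: Metrics
    n_train: int
    n_test: int


@dataclass
class SelfTrainResult:
    model: TrainedModel
    metrics: Metrics
    trace: SelfTrainTrace
    seed_metrics: Metrics  # supervised baseline trained on the seed only
    n_seed: int
    n_unlabelled: int
    n_test: int


def benchmark_corpus(
    seed: int, n_train: int = 500, n_test: int = 200, **config_kwargs
) -> tuple[list[AnnotatedSentence], list[AnnotatedSentence]]:
    """A disjoint sentence-level train/test pair from the generator."""
    config = GeneratorConfig(
        n_sentences=n_train + n_test, seed=seed, **config_kwargs
    )
    corpus = generate_corpus(config)
    rng = random.Random(seed + 1)
    order = list(range(len(corpus)))
    rng.shuffle(order)
    train_set = [corpus[i] for i in order[:n_train]]
    test_set = [corpus[i] for i in order[n_train:]]
    return train_set, test_set


def run_supervised(
    train_corpus: Sequence[AnnotatedSentence],
    test_corpus: Sequence[AnnotatedSentence],
    lexicon: Optional[Lexicon] = None,
    config: TrainConfig = TrainConfig(),
) -> SupervisedResult:
    lexicon = lexicon or default_lexicon()
    train_instances = featurize_corpus(train_corpus, lexicon)
    test_instances = featurize_corpus(test_corpus, lexicon)
    model = train([(i.features, i.label) for i in train_instances], config)
    return SupervisedResult(
        model=model,
        metrics=evaluate_model(model, test_instances),
        n_train=len(train_instances),
        n_test=len(test_instances),
    )


def run_selftrain(
    train_corpus: Sequence[AnnotatedSentence],
    test_corpus: Sequence[AnnotatedSentence],
    config: SelfTrainConfig = SelfTrainConfig(),
    labelled_frac: float = 0.1,
    lexicon: Optional[Lexicon] = None,
) -> SelfTrainResult:
    """Self-training benchmark: a small labelled seed, the rest unlabelled.

    The seed is a sentence-level sample of ``labelled_frac`` of the training
    sentences (so seed and pool never share a sentence); rule labels for the
    pool come from the pattern extractor.
    """
    lexicon = lexicon or default_lexicon()
    rng = random.Random(config.seed + 2)
    order = list(range(len(train_corpus)))
    rng.shuffle(order)
    n_seed = max(1, int(round(labelled_frac * len(train_corpus))))
    seed_corpus = [train_corpus[i] for i in order[:n_seed]]
    pool_corpus = [train_corpus[i] for i in order[n_seed:]]

    labelled = featurize_corpus(seed_corpus, lexicon)
    unlabelled = featurize_corpus(pool_corpus, lexicon)  # labels ignored below
    rule_labels = rule_labels_for_corpus(pool_corpus, lexicon)
    test_instances = featurize_corpus(test_corpus, lexicon)

    seed_model = train(
        [(i.features, i.label) for i in labelled], config.classifier
    )
    model, trace = self_train(labelled, unlabelled, config, rule_labels=rule_labels)
    return SelfTrainResult(
        model=model,
        metrics=evaluate_model(model, test_instances),
        trace=trace,
        seed_metrics=evaluate_model(seed_model, test_instances),
        n_seed=len(labelled),
        n_unlabelled=len(unlabelled),
        n_test=len(test_instances),
    )


def median_over_seeds(values: Sequence[float]) -> float:
    return statistics.median(values)
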