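"""Agreement-based seed bootstrapping and the self-training loop.

The loop starts from a labelled seed and an unlabelled pool of candidate
instances.  Each iteration trains the maxent classifier on the current
labelled set, predicts the pool, and promotes at most ``cap`` instances whose
posterior confidence lies in the inclusive interval [alpha, beta]; during the
first ``rule_iters`` iterations a promoted instance's predicted label must
additionally agree with the rule-based system.  Promoted labels are frozen.
The loop always runs ``max_iters`` iterations (an iteration may promote
nothing), so a run with an empty pool reduces exactly to supervised training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from gprelex.maxent_classifier import (
    Prediction,
    TrainConfig,
    TrainedModel,
    predict,
    train,
)

InstanceKey = tuple[str, str, str]  # (sentence_id, geno_id, pheno_id)


@dataclass(frozen=True)
class LabelledInstance:
    key: InstanceKey
    features: dict[str, float]
    label: str


class SelfTrainError(ValueError):
    pass


@dataclass(frozen=True)
class SelfTrainConfig:
    alpha: float = 0.85  # lower confidence bound (inclusive)
    beta: float = 0.92  # upper confidence bound (inclusive)
    cap: int = 15  # max instances promoted per iteration
    rule_iters: int = 5  # iterations that require rule agreement
    max_iters: int = 6
    seed: int = 0
    classifier: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if not (0.5 <= self.alpha < self.beta <= 1.0):
            raise SelfTrainError(
                f"config error: need 0.5 <= alpha < beta <= 1, got ({self.alpha}, {self.beta})"
            )
        if self.cap < 1:
            raise SelfTrainError("config error: cap must be >= 1")
        if self.rule_iters > self.max_iters:
            raise SelfTrainError("config error: rule_iters must be <= max_iters")
        if self.max_iters < 0:
            raise SelfTrainError("config error: max_iters must be >= 0")


@dataclass
class IterationRecord:
    iteration: int
    n_interval: int  # candidates passing the confidence interval
    n_rule_ok: int  # of those, candidates surviving the rule check
    added: list[tuple[InstanceKey, str, float]]  # (key, label, confidence)
    labelled_size: int  # after the additions of this iteration
    metrics: Optional[dict] = None  # optional held-out metrics


@dataclass
class SelfTrainTrace:
    records: list[IterationRecord] = field(default_factory=list)

    @property
    def total_added(self) -> int:
        return sum(len(r.added) for r in self.records)


@dataclass
class AgreementSeed:
    instances: list[LabelledInstance]  # agreed instances of retained sentences
    retained_sentences: list[str]
    audit: list[str]  # sentence ids with at least one disagreement


def agreement_bootstrap(
    candidates_by_sentence: dict[str, Sequence[InstanceKey]],
    rule_labels: dict[InstanceKey, str],
    model_labels: dict[InstanceKey, str],
    features: dict[InstanceKey, dict[str, float]],
) -> AgreementSeed:
    """Keep instances the rule and model systems agree on; keep a sentence
    when it has at least one agreed positive; route disagreeing sentences to
    the audit list.
    """
    all_keys = {k for keys in candidates_by_sentence.values() for k in keys}
    for name, labels in (("rule", rule_labels), ("model", model_labels)):
        missing = all_keys - set(labels)
        if missing:
            raise SelfTrainError(
                f"{name} labels missing for {len(missing)} candidate instances"
            )
    instances: list[LabelledInstance] = []
    retained: list[str] = []
    audit: list[str] = []
    for sid in sorted(candidates_by_sentence):
        keys = candidates_by_sentence[sid]
        agreed = [(k, rule_labels[k]) for k in keys if rule_labels[k] == model_labels[k]]
        if len(agreed) < len(keys):
            audit.append(sid)
        if any(label == "positive" for _, label in agreed):
            retained.append(sid)
            instances.extend(
                LabelledInstance(key=k, features=features[k], label=label)
                for k, label in agreed
            )
    return AgreementSeed(instances=instances, retained_sentences=retained, audit=audit)


def select_candidates(
    predictions: Sequence[tuple[InstanceKey, Prediction]],
    config: SelfTrainConfig,
    iteration: int,
    rule_labels: Optional[dict[InstanceKey, str]] = None,
) -> tuple[list[tuple[InstanceKey, Prediction]], int, int]:
    """Interval-gated, optionally rule-checked, capped candidate selection.

    Returns ``(selected, n_interval, n_rule_ok)``.  Eligible candidates have
    confidence in [alpha, beta]; during the first ``rule_iters`` iterations
    the predicted label must equal the rule label.  Candidates are ranked by
    confidence descending with the instance key as tie-break, then truncated
    to ``cap``.
    """
    gated = [
        (key, pred)
        for key, pred in predictions
        if config.alpha <= pred.confidence <= config.beta
    ]
    if iteration <= config.rule_iters:
        if rule_labels is None:
            raise SelfTrainError(
                f"rule labels required during the first {config.rule_iters} iterations"
            )
        survivors = [(k, p) for k, p in gated if rule_labels.get(k) == p.label]
    else:
        survivors = gated
    ranked = sorted(survivors, key=lambda kp: (-kp[1].confidence, kp[0]))
    return ranked[: config.cap], len(gated), len(survivors)


def self_train(
    labelled: Sequence[LabelledInstance],
    unlabelled: Sequence[LabelledInstance],
    config: SelfTrainConfig,
    rule_labels: Optional[dict[InstanceKey, str]] = None,
    eval_fn: Optional[Callable[[TrainedModel], dict]] = None,
) -> tuple[TrainedModel, SelfTrainTrace]:
    """Run the self-training loop; returns the final model and the trace.

    ``unlabelled`` instances carry features only (their ``label`` field is
    ignored).  ``eval_fn``, when given, is called with each iteration's model
    and its result recorded in the trace.
    """
    labelled = list(labelled)
    pool = {inst.key: inst for inst in unlabelled}
    trace = SelfTrainTrace()
    clf_config = replace(config.classifier, seed=config.seed)

    model = train([(i.features, i.label) for i in labelled], clf_config)
    for iteration in range(1, config.max_iters + 1):
        predictions = [
            (key, predict(model, inst.features)) for key, inst in sorted(pool.items())
        ]
        selected, n_interval, n_rule_ok = select_candidates(
            predictions, config, iteration, rule_labels
        )
        added = []
        for key, pred in selected:
            inst = pool.pop(key)
            labelled.append(
                LabelledInstance(key=key, features=inst.features, label=pred.label)
            )
            added.append((key, pred.label, pred.confidence))
        model = train([(i.features, i.label) for i in labelled], clf_config)
        trace.records.append(
            IterationRecord(
                iteration=iteration,
                n_interval=n_interval,
                n_rule_ok=n_rule_ok,
                added=added,
                labelled_size=len(labelled),
                metrics=eval_fn(model) if eval_fn is not None else None,
            )
        )
    return model, trace


def grid_run(
    labelled: Sequence[LabelledInstance],
    unlabelled: Sequence[LabelledInstance],
    configs: Sequence[SelfTrainConfig],
    test: Sequence[LabelledInstance],
    score_fn: Callable[[TrainedModel, Sequence[LabelledInstance]], dict],
    rule_labels: Optional[dict[InstanceKey, str]] = None,
) -> list[dict]:
    """Per-setting, per-iteration metric trajectories for a config grid."""
    rows: list[dict] = []
    for setting, config in enumerate(configs):
        _, trace = self_train(
            labelled,
            unlabelled,
            config,
            rule_labels=rule_labels,
            eval_fn=lambda model: score_fn(model, test),
        )
        for rec in trace.records:
            row = {
                "setting": setting,
                "alpha": config.alpha,
                "beta": config.beta,
                "cap": config.cap,
                "iteration": rec.iteration,
                "added": len(rec.added),
                "labelled_size": rec.labelled_size,
            }
            row.update(rec.metrics or {})
            rows.append(row)
    return rows
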