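"""Synthetic gold-labelled annotated sentences.

Every stage of the pipeline is testable without downloads: the generator
instantiates hand-authored sentence templates -- each carrying its tokens,
POS tags, collapsed-dialect dependency tree, Penn-style constituency tree,
entity slots, and gold label -- with synthetic genotype/phenotype identifiers
(``GENO_0001``, ``PHENO_0001``, ...).  Template categories:

* the five positive linguistic patterns (verb-linked, preposition-linked,
  relation chained through a nominal on the dependency path,
  "REL between X and Y" coordination, and slash-joined pairs);
* negation sentences (a ``neg`` dependency on the relation word; gold
  negative, although the rule patterns still fire -- the mislabelling the
  classifier must learn away);
* aim statements ("the present study was undertaken to investigate
  whether ...") that mention a would-be relation without asserting it
  (gold negative);
* distractors containing both entity types but no relation trigger.

The default category mix yields roughly two positive instances per negative
one, the skew typical of relation-annotated training sets in this domain.
Trees are template-authored rather than parsed, so generation is fully
deterministic from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from gprelex.corpus_io import (
    AnnotatedSentence,
    EntityMention,
    RelationInstance,
    Token,
)
from gprelex.deptree import ConstTree, DepTree, validate_tree


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_sentences: int = 500
    pattern_mix: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    negation_frac: float = 0.10
    aim_frac: float = 0.08
    distractor_frac: float = 0.15
    n_geno_vocab: int = 200
    n_pheno_vocab: int = 200
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.negation_frac, self.aim_frac, self.distractor_frac, self.label_noise)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise GeneratorError("config error: fractions must lie in [0, 1]")
        if self.negation_frac + self.aim_frac + self.distractor_frac > 1.0:
            raise GeneratorError("config error: special fractions sum above 1")
        if len(self.pattern_mix) != 5 or any(w < 0 for w in self.pattern_mix):
            raise GeneratorError("config error: pattern_mix needs 5 non-negative weights")
        if sum(self.pattern_mix) == 0:
            raise GeneratorError("config error: pattern_mix sums to 0")
        if self.n_sentences < 0:
            raise GeneratorError("config error: n_sentences must be >= 0")


@dataclass(frozen=True)
class Template:
    """A sentence skeleton with entity slots and validated trees.

    ``tokens`` holds ``(word, pos)`` pairs where the word ``<GENO>`` /
    ``<PHENO>`` marks an entity slot and ``<REL>`` a relation-word slot filled
    from ``rel_choices``.  ``entities`` are ``(etype, start, end, head)``
    over token positions.
    """

    id: str
    category: str  # P1..P5 | negation | aim | distractor
    tokens: tuple[tuple[str, str], ...]
    deps: tuple[tuple[int, int, str], ...]
    ctree: str
    entities: tuple[tuple[str, int, int, int], ...]
    gold: str  # positive | negative
    rel_choices: tuple[str, ...] = ()

    def validate(self) -> None:
        tree = DepTree(len(self.tokens), self.deps)
        validate_tree(tree)
        ct = ConstTree.from_bracketed(self.ctree)
        if ct.n_leaves != len(self.tokens):
            raise GeneratorError(f"template {self.id}: constituency leaves mismatch")
        for etype, start, end, head in self.entities:
            if not (0 <= start < end <= len(self.tokens) and start <= head < end):
                raise GeneratorError(f"template {self.id}: bad entity slot")


def _t(*pairs: str) -> tuple[tuple[str, str], ...]:
    # "word/POS"; rsplit so a literal "/" token ("//SYM") parses
    return tuple((w, p) for w, p in (pair.rsplit("/", 1) for pair in pairs))


_TEMPLATES: list[Template] = [
    Template(
        id="p1_verb",
        category="P1",
        tokens=_t("<GENO>/NN", "<REL>/VBZ", "<PHENO>/NN", "./."),
        deps=((-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")),
        ctree="(S (NP (NN <GENO>)) (VP (VBZ <REL>) (NP (NN <PHENO>))) (. .))",
        entities=(("genotype", 0, 1, 0), ("phenotype", 2, 3, 2)),
        gold="positive",
        rel_choices=("causes", "affects", "influences", "induces", "modulates"),
    ),
    Template(
        id="p2_passive_with",
        category="P2",
        tokens=_t("<PHENO>/NN", "is/VBZ", "<REL>/VBN", "with/IN", "<GENO>/NN", "./."),
        deps=(
            (-1, 2, "root"), (2, 0, "nsubjpass"), (2, 1, "auxpass"),
            (2, 4, "prep_with"), (4, 3, "case"), (2, 5, "punct"),
        ),
        ctree=(
            "(S (NP (NN <PHENO>)) (VP (VBZ is) (VP (VBN <REL>)"
            " (PP (IN with) (NP (NN <GENO>))))) (. .))"
        ),
        entities=(("phenotype", 0, 1, 0), ("genotype", 4, 5, 4)),
        gold="positive",
        rel_choices=("associated", "correlated", "linked"),
    ),
    Template(
        id="p2_passive_to",
        category="P2",
        tokens=_t("<PHENO>/NN", "is/VBZ", "<REL>/VBN", "to/TO", "<GENO>/NN", "./."),
        deps=(
            (-1, 2, "root"), (2, 0, "nsubjpass"), (2, 1, "auxpass"),
            (2, 4, "prep_to"), (4, 3, "case"), (2, 5, "punct"),
        ),
        ctree=(
            "(S (NP (NN <PHENO>)) (VP (VBZ is) (VP (VBN <REL>)"
            " (PP (TO to) (NP (NN <GENO>))))) (. .))"
        ),
        entities=(("phenotype", 0, 1, 0), ("genotype", 4, 5, 4)),
        gold="positive",
        rel_choices=("related", "linked"),
    ),
    Template(
        id="p3_nominal_of_with",
        category="P3",
        tokens=_t(
            "The/DT", "<REL>/NN", "of/IN", "<GENO>/NN", "with/IN",
            "<PHENO>/NN", "is/VBZ", "confirmed/VBN", "./.",
        ),
        deps=(
            (-1, 7, "root"), (1, 0, "det"), (7, 1, "nsubjpass"),
            (1, 3, "prep_of"), (3, 2, "case"), (1, 5, "prep_with"),
            (5, 4, "case"), (7, 6, "auxpass"), (7, 8, "punct"),
        ),
        ctree=(
            "(S (NP (NP (DT The) (NN <REL>)) (PP (IN of) (NP (NN <GENO>)))"
            " (PP (IN with) (NP (NN <PHENO>)))) (VP (VBZ is)"
            " (VP (VBN confirmed))) (. .))"
        ),
        entities=(("genotype", 3, 4, 3), ("phenotype", 5, 6, 5)),
        gold="positive",
        rel_choices=("association", "correlation", "linkage"),
    ),
    Template(
        id="p3_expression_by",
        category="P3",
        tokens=_t("<REL>/NN", "of/IN", "<PHENO>/NN", "by/IN", "<GENO>/NN", "./."),
        deps=(
            (-1, 0, "root"), (0, 2, "prep_of"), (2, 1, "case"),
            (0, 4, "prep_by"), (4, 3, "case"), (0, 5, "punct"),
        ),
        ctree=(
            "(NP (NP (NN <REL>)) (PP (IN of) (NP (NN <PHENO>)))"
            " (PP (IN by) (NP (NN <GENO>))) (. .))"
        ),
        entities=(("phenotype", 2, 3, 2), ("genotype", 4, 5, 4)),
        gold="positive",
        rel_choices=("expression", "regulation"),
    ),
    Template(
        id="p4_between_and",
        category="P4",
        tokens=_t(
            "A/DT", "<REL>/NN", "between/IN", "<GENO>/NN", "and/CC",
            "<PHENO>/NN", "was/VBD", "observed/VBN", "./.",
        ),
        deps=(
            (-1, 7, "root"), (1, 0, "det"), (7, 1, "nsubjpass"),
            (1, 3, "prep_between"), (3, 2, "case"), (1, 5, "prep_between"),
            (3, 4, "cc"), (7, 6, "auxpass"), (7, 8, "punct"),
        ),
        ctree=(
            "(S (NP (NP (DT A) (NN <REL>)) (PP (IN between) (NP (NP (NN <GENO>))"
            " (CC and) (NP (NN <PHENO>))))) (VP (VBD was) (VP (VBN observed))) (. .))"
        ),
        entities=(("genotype", 3, 4, 3), ("phenotype", 5, 6, 5)),
        gold="positive",
        rel_choices=("correlation", "association", "relationship"),
    ),
    Template(
        id="p5_slash",
        category="P5",
        tokens=_t("<GENO>/NN", "//SYM", "<PHENO>/NN", "<REL>/NN", "./."),
        deps=(
            (-1, 3, "root"), (3, 0, "nn"), (3, 1, "punct"),
            (3, 2, "nn"), (3, 4, "punct"),
        ),
        ctree="(NP (NN <GENO>) (SYM /) (NN <PHENO>) (NN <REL>) (. .))",
        entities=(("genotype", 0, 1, 0), ("phenotype", 2, 3, 2)),
        gold="positive",
        rel_choices=("correlation", "association"),
    ),
    Template(
        id="neg_no_correlation",
        category="negation",
        tokens=_t(
            "no/DT", "<REL>/NN", "in/IN", "patients/NNS", "with/IN", "<PHENO>/NN",
            "with/IN", "the/DT", "<GENO>/NN", "gene/NN", "was/VBD", "found/VBN", "./.",
        ),
        deps=(
            (-1, 11, "root"), (11, 1, "nsubjpass"), (1, 0, "neg"),
            (1, 3, "prep_in"), (3, 2, "case"), (3, 5, "prep_with"), (5, 4, "case"),
            (1, 9, "prep_with"), (9, 6, "case"), (9, 7, "det"), (9, 8, "nn"),
            (11, 10, "auxpass"), (11, 12, "punct"),
        ),
        ctree=(
            "(S (NP (NP (DT no) (NN <REL>)) (PP (IN in) (NP (NP (NNS patients))"
            " (PP (IN with) (NP (NN <PHENO>))))) (PP (IN with) (NP (DT the)"
            " (NN <GENO>) (NN gene)))) (VP (VBD was) (VP (VBN found))) (. .))"
        ),
        entities=(("phenotype", 5, 6, 5), ("genotype", 8, 10, 9)),
        gold="negative",
        rel_choices=("correlation", "association"),
    ),
    Template(
        id="neg_not_associated",
        category="negation",
        tokens=_t(
            "<PHENO>/NN", "was/VBD", "not/RB", "<REL>/VBN", "with/IN", "<GENO>/NN", "./.",
        ),
        deps=(
            (-1, 3, "root"), (3, 0, "nsubjpass"), (3, 1, "auxpass"),
            (3, 2, "neg"), (3, 5, "prep_with"), (5, 4, "case"), (3, 6, "punct"),
        ),
        ctree=(
            "(S (NP (NN <PHENO>)) (VP (VBD was) (RB not) (VP (VBN <REL>)"
            " (PP (IN with) (NP (NN <GENO>))))) (. .))"
        ),
        entities=(("phenotype", 0, 1, 0), ("genotype", 5, 6, 5)),
        gold="negative",
        rel_choices=("associated", "correlated"),
    ),
    Template(
        id="aim_study",
        category="aim",
        tokens=_t(
            "The/DT", "present/JJ", "study/NN", "was/VBD", "undertaken/VBN",
            "to/TO", "investigate/VB", "whether/IN", "<GENO>/NN", "is/VBZ",
            "associated/VBN", "with/IN", "<PHENO>/NN", "./.",
        ),
        deps=(
            (-1, 4, "root"), (4, 2, "nsubjpass"), (2, 0, "det"), (2, 1, "amod"),
            (4, 3, "auxpass"), (4, 6, "xcomp"), (6, 5, "aux"), (6, 10, "ccomp"),
            (10, 7, "mark"), (10, 8, "nsubjpass"), (10, 9, "auxpass"),
            (10, 12, "prep_with"), (12, 11, "case"), (4, 13, "punct"),
        ),
        ctree=(
            "(S (NP (DT The) (JJ present) (NN study)) (VP (VBD was)"
            " (VP (VBN undertaken) (S (VP (TO to) (VP (VB investigate)"
            " (SBAR (IN whether) (S (NP (NN <GENO>)) (VP (VBZ is)"
            " (VP (VBN associated) (PP (IN with) (NP (NN <PHENO>)))))))))))) (. .))"
        ),
        entities=(("genotype", 8, 9, 8), ("phenotype", 12, 13, 12)),
        gold="negative",
    ),
    Template(
        id="dist_sequenced_recorded",
        category="distractor",
        tokens=_t(
            "<GENO>/NN", "was/VBD", "sequenced/VBN", "and/CC",
            "<PHENO>/NN", "was/VBD", "recorded/VBN", "./.",
        ),
        deps=(
            (-1, 2, "root"), (2, 0, "nsubjpass"), (2, 1, "auxpass"),
            (2, 6, "conj_and"), (6, 3, "cc"), (6, 4, "nsubjpass"),
            (6, 5, "auxpass"), (2, 7, "punct"),
        ),
        ctree=(
            "(S (S (NP (NN <GENO>)) (VP (VBD was) (VP (VBN sequenced))))"
            " (CC and) (S (NP (NN <PHENO>)) (VP (VBD was) (VP (VBN recorded)))) (. .))"
        ),
        entities=(("genotype", 0, 1, 0), ("phenotype", 4, 5, 4)),
        gold="negative",
    ),
    Template(
        id="dist_recruited",
        category="distractor",
        tokens=_t(
            "Patients/NNS", "with/IN", "<PHENO>/NN", "and/CC", "carriers/NNS",
            "of/IN", "<GENO>/NN", "were/VBD", "recruited/VBN", "./.",
        ),
        deps=(
            (-1, 8, "root"), (8, 0, "nsubjpass"), (0, 2, "prep_with"),
            (2, 1, "case"), (0, 4, "conj_and"), (4, 3, "cc"),
            (4, 6, "prep_of"), (6, 5, "case"), (8, 7, "auxpass"), (8, 9, "punct"),
        ),
        ctree=(
            "(S (NP (NP (NNS Patients)) (PP (IN with) (NP (NN <PHENO>)))"
            " (CC and) (NP (NP (NNS carriers)) (PP (IN of) (NP (NN <GENO>)))))"
            " (VP (VBD were) (VP (VBN recruited))) (. .))"
        ),
        entities=(("phenotype", 2, 3, 2), ("genotype", 6, 7, 6)),
        gold="negative",
    ),
    Template(
        id="dist_genotyping",
        category="distractor",
        tokens=_t(
            "<GENO>/NN", "genotyping/NN", "was/VBD", "performed/VBN", "across/IN",
            "patients/NNS", "with/IN", "<PHENO>/NN", "./.",
        ),
        deps=(
            (-1, 3, "root"), (3, 1, "nsubjpass"), (1, 0, "nn"), (3, 2, "auxpass"),
            (3, 5, "prep_across"), (5, 4, "case"), (5, 7, "prep_with"),
            (7, 6, "case"), (3, 8, "punct"),
        ),
        ctree=(
            "(S (NP (NN <GENO>) (NN genotyping)) (VP (VBD was) (VP (VBN performed)"
            " (PP (IN across) (NP (NP (NNS patients)) (PP (IN with)"
            " (NP (NN <PHENO>))))))) (. .))"
        ),
        entities=(("genotype", 0, 1, 0), ("phenotype", 7, 8, 7)),
        gold="negative",
    ),
]


def list_templates() -> list[Template]:
    """The validated template catalogue."""
    for template in _TEMPLATES:
        template.validate()
    return list(_TEMPLATES)


_BY_CATEGORY: dict[str, list[Template]] = {}
for _tpl in _TEMPLATES:
    _BY_CATEGORY.setdefault(_tpl.category, []).append(_tpl)


def _instantiate(
    template: Template, sid: str, rng: random.Random, config: GeneratorConfig
) -> AnnotatedSentence:
    geno = f"GENO_{rng.randrange(config.n_geno_vocab):04d}"
    pheno = f"PHENO_{rng.randrange(config.n_pheno_vocab):04d}"
    rel = rng.choice(template.rel_choices) if template.rel_choices else None
    substitution = {"<GENO>": geno, "<PHENO>": pheno, "<REL>": rel}

    tokens = []
    for i, (word, pos) in enumerate(template.tokens):
        surface = substitution.get(word, word)
        assert surface is not None
        tokens.append(Token(index=i, surface=surface, pos=pos))
    ctree_text = template.ctree
    for slot, value in substitution.items():
        if value is not None:
            ctree_text = ctree_text.replace(slot, value)
    entities = []
    counters = {"genotype": 0, "phenotype": 0}
    for etype, start, end, head in template.entities:
        prefix = "g" if etype == "genotype" else "p"
        entities.append(
            EntityMention(
                id=f"{prefix}{counters[etype]}", etype=etype,
                start=start, end=end, head_index=head,
            )
        )
        counters[etype] += 1

    label = template.gold
    if config.label_noise > 0 and rng.random() < config.label_noise:
        label = "negative" if label == "positive" else "positive"
    relations = [
        RelationInstance(sid, g.id, p.id, label=label, provenance="gold")
        for g in entities if g.etype == "genotype"
        for p in entities if p.etype == "phenotype"
    ]
    return AnnotatedSentence(
        id=sid,
        tokens=tokens,
        entities=entities,
        deps=DepTree(len(tokens), template.deps),
        ctree=ConstTree.from_bracketed(ctree_text),
        gold_relations=relations,
    )


def worked_example() -> AnnotatedSentence:
    """The standard worked dependency-path example.

    "The association of Genotype1 with Phenotype2 is confirmed." -- the
    path between the entities is
    Genotype1-prep_of-association-prep_with-Phenotype2 and "association"
    is the relationship term at its root.
    """
    template = next(t for t in _TEMPLATES if t.id == "p3_nominal_of_with")
    substitution = {"<GENO>": "Genotype1", "<PHENO>": "Phenotype2", "<REL>": "association"}
    tokens = [
        Token(index=i, surface=substitution.get(word, word), pos=pos)
        for i, (word, pos) in enumerate(template.tokens)
    ]
    ctree_text = template.ctree
    for slot, value in substitution.items():
        ctree_text = ctree_text.replace(slot, value)
    entities = [
        EntityMention(id="g0", etype="genotype", start=3, end=4, head_index=3),
        EntityMention(id="p0", etype="phenotype", start=5, end=6, head_index=5),
    ]
    return AnnotatedSentence(
        id="worked_example",
        tokens=tokens,
        entities=entities,
        deps=DepTree(len(tokens), template.deps),
        ctree=ConstTree.from_bracketed(ctree_text),
        gold_relations=[
            RelationInstance("worked_example", "g0", "p0", label="positive", provenance="gold")
        ],
    )


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedSentence]:
    """Generate ``n_sentences`` gold-labelled sentences, reproducibly."""
    rng = random.Random(config.seed)
    patterns = ("P1", "P2", "P3", "P4", "P5")
    sentences = []
    for i in range(config.n_sentences):
        u = rng.random()
        if u < config.negation_frac:
            category = "negation"
        elif u < config.negation_frac + config.aim_frac:
            category = "aim"
        elif u < config.negation_frac + config.aim_frac + config.distractor_frac:
            category = "distractor"
        else:
            category = rng.choices(patterns, weights=config.pattern_mix)[0]
        template = rng.choice(_BY_CATEGORY[category])
        sentences.append(_instantiate(template, f"s{i:05d}", rng, config))
    return sentences
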