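"""Instance feature extraction for the maxent relation classifier.

For one (genotype mention, phenotype mention) candidate the extractor emits a
sparse binary feature vector drawn from nine named families:

====================  ======================================================
family                content
====================  ======================================================
``relterm``           relationship term at the dependency-path root, its
                      stem, its position relative to the mentions, and its
                      grammatical role (the path edge labels on the genotype
                      and phenotype sides of the root)
``keyterm``           the key term from the four-step precedence procedure
                      and its relative position
``collapsed1``        collapsed dependency path, version 1
                      (nsubj/nsubjpass -> subj, rcmod/partmod -> mod,
                      prep_x -> x, everything else -> the placeholder O)
``collapsed2``        collapsed dependency path, version 2 (prep_* only)
``neg``               whether any path node dominates a ``neg`` dependency
``dblbetween``        two consecutive ``prep_between`` links on the path
``synlca``            stem of the constituency LCA head when it is a
                      relationship term, else NULL
``synpath``           constituent label x distance chains from the LCA down
                      to each entity
``surf``              lexicon terms between the mentions or within a
                      4-token window outside them, with their position
====================  ======================================================

Path-content families (``collapsed*``, ``neg``, ``dblbetween``, ``relterm``
value/stem/position, ``keyterm``, ``surf``, ``syn*``) are computed on the
linearly-first-to-second mention path and are invariant under swapping which
mention is the genotype; only the role-encoding ``relterm:dep`` feature is
anchored to entity types.
"""

from __future__ import annotations

from typing import Optional

from gprelex.corpus_io import AnnotatedSentence, Lexicon, RelationInstance
from gprelex.deptree import (
    DepPath,
    DepTree,
    const_lca,
    dependency_path,
    dominates_or_self,
    path_to_lca,
)
from gprelex.stemming import stem as _porter

FEATURE_FAMILIES = frozenset(
    {"relterm", "keyterm", "collapsed1", "collapsed2", "neg", "dblbetween",
     "synlca", "synpath", "surf"}
)

SURFACE_WINDOW = 4  # tokens; the outside window is inclusive of the 4th token

NONE_SENTINEL = "NONE"
NULL_SENTINEL = "NULL"


def stem(word: str) -> str:
    """Porter stem, lowercased; re-exported for the lexicon contract."""
    return _porter(word)


def feature_family(name: str) -> str:
    return name.split(":", 1)[0].split("=", 1)[0]


# ---------------------------------------------------------------------------
# positions and mention ordering
# ---------------------------------------------------------------------------


def _ordered_mentions(sentence: AnnotatedSentence, pair: RelationInstance):
    geno = sentence.entity(pair.geno_id)
    pheno = sentence.entity(pair.pheno_id)
    first, second = sorted((geno, pheno), key=lambda e: (e.start, e.id))
    return geno, pheno, first, second


def relative_position(token_index: int, first, second) -> str:
    """before / between / after relative to the linearly ordered mentions."""
    if token_index < first.start:
        return "before"
    if token_index >= second.end:
        return "after"
    return "between"


# ---------------------------------------------------------------------------
# dependency features
# ---------------------------------------------------------------------------


def path_relationship_term(
    path: DepPath, sentence: AnnotatedSentence, lexicon: Lexicon
) -> Optional[str]:
    """Surface form of the path root when its stem is in the lexicon."""
    surface = sentence.tokens[path.path_root].surface
    return surface if surface in lexicon else None


def collapse_path(path: DepPath, version: int) -> tuple[str, ...]:
    """Collapse the path's edge labels.

    Version 1 rewrites every label (nsubj/nsubjpass -> subj, rcmod/partmod ->
    mod, prep_x -> x, everything else -> the placeholder ``O``); version 2
    keeps only the ``prep_*`` labels, stripped of the prefix.
    """
    if version == 1:
        out = []
        for label in path.label_names:
            if label in ("nsubj", "nsubjpass"):
                out.append("subj")
            elif label in ("rcmod", "partmod"):
                out.append("mod")
            elif label.startswith("prep_"):
                out.append(label[len("prep_"):])
            else:
                out.append("O")
        return tuple(out)
    if version == 2:
        return tuple(
            label[len("prep_"):] for label in path.label_names if label.startswith("prep_")
        )
    raise ValueError(f"unknown collapse version {version}")


def has_negative_dependency(path: DepPath, tree: DepTree) -> bool:
    """True iff some node on the path dominates a ``neg`` dependency."""
    neg_dependents = [d for h, d, l in tree.edges if l == "neg"]
    if not neg_dependents:
        return False
    on_path = set(path.nodes)
    for dep in neg_dependents:
        # the neg edge's head and all its ancestors dominate the neg relation
        for node in tree.head_chain(dep)[1:]:
            if node in on_path:
                return True
    return False


def has_double_prep_between(path: DepPath) -> bool:
    labels = path.label_names
    return any(
        labels[i] == "prep_between" and labels[i + 1] == "prep_between"
        for i in range(len(labels) - 1)
    )


# ---------------------------------------------------------------------------
# key term (four-step precedence procedure)
# ---------------------------------------------------------------------------


def find_key_term(
    sentence: AnnotatedSentence, pair: RelationInstance, lexicon: Lexicon
) -> Optional[tuple[int, int]]:
    """The relationship term that best describes the candidate interaction.

    Returns ``(token_index, step)`` or ``None``.  Steps, in precedence order:

    1. a relationship term linearly between the mentions that dominates both
       entity heads (dominance taken as ancestor-or-self);
    2. a word between the mentions dominating both whose dependency child is
       a relationship term -- that child is the key term;
    3. as step 1, but the term lies left of the first mention or right of the
       second;
    4. as step 2, on the outside.

    When several terms qualify within one step, the one closest to the
    midpoint of the mention pair wins; ties break leftward.
    """
    if sentence.deps is None:
        raise ValueError(f"{sentence.id}: dependency tree required for key term")
    tree = sentence.deps
    _, _, first, second = _ordered_mentions(sentence, pair)
    heads = (first.head, second.head)
    between = range(first.end, second.start)
    outside = [i for i in range(len(sentence.tokens))
               if i < first.start or i >= second.end]
    midpoint = (first.start + second.end - 1) / 2.0

    def best(candidates: list[int]) -> Optional[int]:
        if not candidates:
            return None
        return min(candidates, key=lambda i: (abs(i - midpoint), i))

    def dominates_both(i: int) -> bool:
        return all(dominates_or_self(tree, i, h) for h in heads)

    # step 1 / 3: the term itself dominates both entities
    for step, region in ((1, list(between)), (3, outside)):
        hits = [
            i for i in region
            if sentence.tokens[i].surface in lexicon and dominates_both(i)
        ]
        choice = best(hits)
        if choice is not None:
            return choice, step
        # step 2 / 4: a dominating word whose child is a relationship term
        child_hits = [
            child
            for i in region
            if dominates_both(i)
            for child, _ in tree.children(i)
            if sentence.tokens[child].surface in lexicon
        ]
        choice = best(child_hits)
        if choice is not None:
            return choice, step + 1
    return None


# ---------------------------------------------------------------------------
# feature-family fragments
# ---------------------------------------------------------------------------


def dependency_features(
    sentence: AnnotatedSentence, pair: RelationInstance, lexicon: Lexicon
) -> dict[str, float]:
    tree = sentence.deps
    if tree is None:
        raise ValueError(f"{sentence.id}: dependency tree required")
    geno, pheno, first, second = _ordered_mentions(sentence, pair)
    path = dependency_path(tree, first.head, second.head)
    feats: dict[str, float] = {}

    term = path_relationship_term(path, sentence, lexicon)
    if term is None:
        feats[f"relterm={NONE_SENTINEL}"] = 1.0
        feats[f"relterm:stem={NONE_SENTINEL}"] = 1.0
    else:
        feats[f"relterm={term.lower()}"] = 1.0
        feats[f"relterm:stem={stem(term)}"] = 1.0
        feats[f"relterm:pos={relative_position(path.path_root, first, second)}"] = 1.0
        # grammatical role of the term: path edge labels on each entity side
        gp_path = dependency_path(tree, geno.head, pheno.head)
        i = gp_path.root_pos
        geno_side = gp_path.labels[i - 1][0] if i > 0 else "self"
        pheno_side = gp_path.labels[i][0] if i < len(gp_path.labels) else "self"
        feats[f"relterm:dep=geno:{geno_side}|pheno:{pheno_side}"] = 1.0

    key = find_key_term(sentence, pair, lexicon)
    if key is None:
        feats[f"keyterm={NONE_SENTINEL}"] = 1.0
    else:
        idx, _step = key
        feats[f"keyterm={stem(sentence.tokens[idx].surface)}"] = 1.0
        feats[f"keyterm:pos={relative_position(idx, first, second)}"] = 1.0

    feats["collapsed1=" + "|".join(collapse_path(path, 1))] = 1.0
    v2 = collapse_path(path, 2)
    feats["collapsed2=" + ("|".join(v2) if v2 else NONE_SENTINEL)] = 1.0
    feats[f"neg={str(has_negative_dependency(path, tree)).lower()}"] = 1.0
    feats[f"dblbetween={str(has_double_prep_between(path)).lower()}"] = 1.0
    return feats


def syntactic_features(
    sentence: AnnotatedSentence, pair: RelationInstance, lexicon: Lexicon
) -> dict[str, float]:
    """LCA-head and constituent-path features from the constituency tree."""
    if sentence.ctree is None:
        return {"synlca:noctree": 1.0}
    _, _, first, second = _ordered_mentions(sentence, pair)
    lca = const_lca(sentence.ctree, first.span, second.span)
    head = sentence.ctree.head_word(lca)
    value = stem(head) if head in lexicon else NULL_SENTINEL
    feats = {f"synlca={value}": 1.0}
    for tag, span in (("first", first.span), ("second", second.span)):
        for label, dist in path_to_lca(sentence.ctree, span, lca):
            feats[f"synpath:{tag}={label}|{dist}"] = 1.0
    return feats


def surface_features(
    sentence: AnnotatedSentence, pair: RelationInstance, lexicon: Lexicon
) -> dict[str, float]:
    """Lexicon terms between the mentions or within the 4-token outer window."""
    _, _, first, second = _ordered_mentions(sentence, pair)
    feats: dict[str, float] = {}
    n = len(sentence.tokens)
    candidates = set(range(first.end, second.start))
    candidates |= set(range(max(0, first.start - SURFACE_WINDOW), first.start))
    candidates |= set(range(second.end, min(n, second.end + SURFACE_WINDOW)))
    for i in sorted(candidates):
        surface = sentence.tokens[i].surface
        if surface in lexicon:
            pos = relative_position(i, first, second)
            feats[f"surf={stem(surface)}|{pos}"] = 1.0
    return feats


def extract_features(
    sentence: AnnotatedSentence, pair: RelationInstance, lexicon: Lexicon
) -> dict[str, float]:
    """Union of the dependency, syntactic, and surface feature fragments."""
    feats = dependency_features(sentence, pair, lexicon)
    feats.update(syntactic_features(sentence, pair, lexicon))
    feats.update(surface_features(sentence, pair, lexicon))
    return feats
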