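"""Rule-based relationship identification via five linguistic patterns.

With REL any relationship-lexicon term, PREP a preposition from the closed
set {of, by, to, on, for, in, through, with} (plus "between" for P4), and N a
noun, the patterns are:

P1  Entity1 REL Entity2                       "G causes P"
P2  Entity1 REL PREP+ Entity2                 "P is associated with G"
P3  preposition-chained relation through a    "expression of P by G",
    relationship term on the dependency path  "the association of G with P"
P4  REL PREP Entity1 and Entity2              "correlation between G and P"
P5  Entity1 (/ | \\ | -) Entity2 with a nearby "G/P correlation"
    relationship term

P1, P2, P4 and P5 are token-sequence matchers over the region between and
around the mentions; P3 is matched on the collapsed dependency path (every
interior node a relationship term or a noun, at least one interior
relationship term, at least one ``prep_*`` edge from the closed preposition
set, at most ``P3_MAX_EDGES`` edges).  A candidate pair is reported at most
once: the first matching pattern in the order P1..P5 wins.

Negation is deliberately not vetoed by default -- general-purpose relation
tools of this family treat "no correlation ..." as a positive match, and the
classifier is left to learn negation from the ``neg`` dependency feature.  An
optional ``veto_neg`` flag suppresses matches whose path dominates a ``neg``
edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from gprelex.corpus_io import (
    AnnotatedSentence,
    Lexicon,
    P4_PREPOSITIONS,
    P_PREPOSITIONS,
    RelationInstance,
    candidate_pairs,
)
from gprelex.deptree import dependency_path
from gprelex.feature_extraction import has_negative_dependency

AUXILIARIES = frozenset(
    {"is", "are", "was", "were", "be", "been", "being", "has", "have", "had"}
)
P5_SEPARATORS = frozenset({"/", "\\", "-", "–"})
P5_WINDOW = 4
P3_MAX_EDGES = 6  # cap on the matched dependency-path chain

PATTERN_IDS = ("P1", "P2", "P3", "P4", "P5")


@dataclass(frozen=True)
class PatternMatch:
    instance: RelationInstance
    pattern_id: str
    trigger: int  # token index of the matched relationship term


def _is_nounish(token) -> bool:
    # unknown POS is treated as nominal so that plain-token fixtures work
    return token.pos is None or token.pos.startswith("N")


def _p1(sentence, lexicon, first, second) -> Optional[int]:
    between = list(range(first.end, second.start))
    if len(between) == 1 and sentence.tokens[between[0]].surface in lexicon:
        return between[0]
    return None


def _p2(sentence, lexicon, first, second) -> Optional[int]:
    """Between region = (auxiliaries)* REL+ PREP+ with the closed PREP set."""
    content = [
        i for i in range(first.end, second.start)
        if sentence.tokens[i].surface.lower() not in AUXILIARIES
    ]
    if len(content) < 2:
        return None
    k = 0
    while k < len(content) and sentence.tokens[content[k]].surface in lexicon:
        k += 1
    if k == 0:
        return None
    rest = content[k:]
    if not rest:
        return None
    if all(sentence.tokens[i].surface.lower() in P_PREPOSITIONS for i in rest):
        return content[k - 1]
    return None


def _p3(sentence, lexicon, first, second) -> Optional[int]:
    path = dependency_path(sentence.deps, first.head, second.head)
    if not (2 <= len(path.labels) <= P3_MAX_EDGES):
        return None
    interior = path.nodes[1:-1]
    trigger = None
    for node in interior:
        tok = sentence.tokens[node]
        if tok.surface in lexicon:
            if trigger is None:
                trigger = node
        elif not _is_nounish(tok):
            return None
    if trigger is None:
        return None
    preps = [l for l in path.label_names if l.startswith("prep_")]
    if not preps:
        return None
    if any(l[len("prep_"):] not in P_PREPOSITIONS for l in preps):
        return None  # prep_between chains belong to P4
    return trigger


def _p4(sentence, lexicon, first, second) -> Optional[int]:
    if first.start < 2:
        return None
    prep = sentence.tokens[first.start - 1].surface.lower()
    rel = sentence.tokens[first.start - 2].surface
    between = [sentence.tokens[i].surface.lower() for i in range(first.end, second.start)]
    if prep in P4_PREPOSITIONS and rel in lexicon and between == ["and"]:
        return first.start - 2
    return None


def _p5(sentence, lexicon, first, second) -> Optional[int]:
    between = list(range(first.end, second.start))
    if len(between) != 1 or sentence.tokens[between[0]].surface not in P5_SEPARATORS:
        return None
    n = len(sentence.tokens)
    window = list(range(max(0, first.start - P5_WINDOW), first.start))
    window += list(range(second.end, min(n, second.end + P5_WINDOW)))
    for i in window:
        if sentence.tokens[i].surface in lexicon:
            return i
    return None


_MATCHERS = (("P1", _p1), ("P2", _p2), ("P3", _p3), ("P4", _p4), ("P5", _p5))


def match_patterns(
    sentence: AnnotatedSentence, lexicon: Lexicon, veto_neg: bool = False
) -> list[PatternMatch]:
    """All pattern matches in a sentence, one at most per candidate pair."""
    if sentence.deps is None:
        raise ValueError(f"{sentence.id}: dependency tree required for rule matching")
    if len(lexicon) == 0:
        raise ValueError("non-empty lexicon required")
    matches = []
    for cand in candidate_pairs(sentence):
        geno = sentence.entity(cand.geno_id)
        pheno = sentence.entity(cand.pheno_id)
        first, second = sorted((geno, pheno), key=lambda e: (e.start, e.id))
        for pattern_id, matcher in _MATCHERS:
            trigger = matcher(sentence, lexicon, first, second)
            if trigger is None:
                continue
            if veto_neg:
                path = dependency_path(sentence.deps, first.head, second.head)
                if has_negative_dependency(path, sentence.deps):
                    break
            matches.append(
                PatternMatch(
                    instance=RelationInstance(
                        sentence_id=sentence.id,
                        geno_id=cand.geno_id,
                        pheno_id=cand.pheno_id,
                        label="positive",
                        provenance="rule",
                    ),
                    pattern_id=pattern_id,
                    trigger=trigger,
                )
            )
            break
    return matches


def rule_label(
    sentence: AnnotatedSentence,
    pair: RelationInstance,
    lexicon: Lexicon,
    veto_neg: bool = False,
) -> str:
    """positive iff some pattern match covers the pair, else negative."""
    keys = {c.key for c in candidate_pairs(sentence)}
    if pair.key not in keys:
        raise ValueError(f"pair {pair.key} is not a candidate of sentence {sentence.id}")
    matched = {m.instance.key for m in match_patterns(sentence, lexicon, veto_neg=veto_neg)}
    return "positive" if pair.key in matched else "negative"


def rule_labels_for_corpus(
    corpus, lexicon: Lexicon, veto_neg: bool = False
) -> dict[tuple[str, str, str], str]:
    """Rule label for every candidate pair of every sentence."""
    out: dict[tuple[str, str, str], str] = {}
    for sentence in corpus:
        matched = {m.instance.key for m in match_patterns(sentence, lexicon, veto_neg=veto_neg)}
        for cand in candidate_pairs(sentence):
            out[cand.key] = "positive" if cand.key in matched else "negative"
    return out
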