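"""Feature extraction: path features, key-term procedure, windows, purity."""

import random

import pytest

from gprelex.corpus_io import (
    AnnotatedSentence,
    EntityMention,
    Lexicon,
    Token,
    candidate_pairs,
)
from gprelex.deptree import DepPath, DepTree, dependency_path, dominates_or_self
from gprelex.feature_extraction import (
    FEATURE_FAMILIES,
    collapse_path,
    extract_features,
    feature_family,
    find_key_term,
    has_double_prep_between,
    has_negative_dependency,
    path_relationship_term,
    relative_position,
    surface_features,
    syntactic_features,
)


def build(words, deps, entities, sid="s0", pos=None, ctree=None):
    from gprelex.deptree import ConstTree

    tokens = [
        Token(index=i, surface=w, pos=(pos[i] if pos else None))
        for i, w in enumerate(words)
    ]
    return AnnotatedSentence(
        id=sid, tokens=tokens, entities=entities, deps=DepTree(len(words), deps),
        ctree=ConstTree.from_bracketed(ctree) if ctree else None,
    )


def geno(start, eid="g0"):
    return EntityMention(eid, "genotype", start, start + 1)


def pheno(start, eid="p0"):
    return EntityMention(eid, "phenotype", start, start + 1)


def pair_of(sentence):
    [p] = candidate_pairs(sentence)
    return p


# ---------------------------------------------------------------------------
# relationship term at the path root
# ---------------------------------------------------------------------------


def test_worked_example_relationship_term(fig_sentence, lexicon):
    path = dependency_path(fig_sentence.deps, 3, 5)
    assert path_relationship_term(path, fig_sentence, lexicon) == "association"


def test_non_lexicon_root_yields_none(lexicon):
    sent = build(
        ["GENO1", "patients", "PHENO1"],
        [(-1, 1, "root"), (1, 0, "nn"), (1, 2, "nn")],
        [geno(0), pheno(2)],
    )
    path = dependency_path(sent.deps, 0, 2)
    assert path_relationship_term(path, sent, lexicon) is None


def test_relterm_position_before(fig_sentence, lexicon):
    # "association" at token 1; entities at 3 and 5
    feats = extract_features(fig_sentence, pair_of(fig_sentence), lexicon)
    assert "relterm:pos=before" in feats


# ---------------------------------------------------------------------------
# collapsed paths
# ---------------------------------------------------------------------------


def _path(labels):
    n = len(labels) + 1
    nodes = tuple(range(n))
    return DepPath(nodes, tuple((l, "down") for l in labels), 0)


@pytest.mark.parametrize(
    "labels,version,expected",
    [
        (("prep_of", "prep_with"), 1, ("of", "with")),
        (("nsubjpass", "prep_with"), 1, ("subj", "with")),
        (("nsubjpass", "prep_with"), 2, ("with",)),
        (("det", "amod"), 2, ()),
        (("rcmod", "partmod", "dobj"), 1, ("mod", "mod", "O")),
        (("nsubj",), 1, ("subj",)),
    ],
)
def test_collapse_rules(labels, version, expected):
    assert collapse_path(_path(labels), version) == expected


def test_collapse_v1_length_and_v2_subsequence():
    rng = random.Random(5)
    labels = ["nsubj", "nsubjpass", "rcmod", "partmod", "prep_of", "prep_between", "dobj", "det", "neg"]
    for _ in range(50):
        ls = tuple(rng.choice(labels) for _ in range(rng.randint(1, 7)))
        p = _path(ls)
        v1 = collapse_path(p, 1)
        v2 = collapse_path(p, 2)
        assert len(v1) == len(ls)
        # v2 equals v1 restricted to the prep positions
        assert list(v2) == [v1[i] for i, l in enumerate(ls) if l.startswith("prep_")]


# ---------------------------------------------------------------------------
# negation and double prep_between
# ---------------------------------------------------------------------------


def test_negative_dependency_detected_on_printed_negation_fixture(lexicon):
    words = ["no", "correlation", "in", "patients", "with", "PHENO1",
             "with", "the", "GENO1", "gene", "was", "found", "."]
    deps = [(-1, 11, "root"), (11, 1, "nsubjpass"), (1, 0, "neg"),
            (1, 3, "prep_in"), (3, 2, "case"), (3, 5, "prep_with"), (5, 4, "case"),
            (1, 9, "prep_with"), (9, 6, "case"), (9, 7, "det"), (9, 8, "nn"),
            (11, 10, "auxpass"), (11, 12, "punct")]
    sent = build(words, deps, [pheno(5), EntityMention("g0", "genotype", 8, 10, 9)])
    path = dependency_path(sent.deps, 5, 9)
    assert has_negative_dependency(path, sent.deps)


def test_no_negation_on_worked_example(fig_sentence):
    path = dependency_path(fig_sentence.deps, 3, 5)
    assert not has_negative_dependency(path, fig_sentence.deps)


def test_neg_edge_outside_path_subtrees_not_flagged():
    # neg attached under the root but outside every path node's subtree
    words = ["not", "seen", "GENO1", "link", "PHENO1"]
    deps = [(-1, 1, "root"), (1, 0, "neg"), (1, 3, "dobj"),
            (3, 2, "nn"), (3, 4, "nn")]
    sent = build(words, deps, [geno(2), pheno(4)])
    path = dependency_path(sent.deps, 2, 4)  # 2 - 3 - 4, root token 1 not on path
    assert not has_negative_dependency(path, sent.deps)


def test_double_prep_between():
    assert has_double_prep_between(_path(("prep_between", "prep_between")))
    assert not has_double_prep_between(_path(("prep_between", "conj_and")))
    rng = random.Random(9)
    labels = ["prep_between", "conj_and", "nsubj", "prep_of"]
    for _ in range(100):
        ls = tuple(rng.choice(labels) for _ in range(rng.randint(0, 6)))
        expected = any(
            ls[i] == ls[i + 1] == "prep_between" for i in range(len(ls) - 1)
        )
        assert has_double_prep_between(_path(ls)) == expected


# ---------------------------------------------------------------------------
# key term
# ---------------------------------------------------------------------------


def brute_force_key_term(sentence, pair, lexicon):
    """Independent oracle: enumerate tokens x dominance with step precedence."""
    tree = sentence.deps
    g = sentence.entity(pair.geno_id)
    p = sentence.entity(pair.pheno_id)
    first, second = sorted((g, p), key=lambda e: (e.start, e.id))
    heads = (first.head, second.head)
    mid = (first.start + second.end - 1) / 2.0
    n = len(sentence.tokens)
    between = [i for i in range(n) if first.end <= i < second.start]
    outside = [i for i in range(n) if i < first.start or i >= second.end]

    def dom_both(i):
        return all(dominates_or_self(tree, i, h) for h in heads)

    def pick(cands):
        return min(cands, key=lambda i: (abs(i - mid), i)) if cands else None

    for step, region in ((1, between), (3, outside)):
        direct = [i for i in region if sentence.tokens[i].surface in lexicon and dom_both(i)]
        if pick(direct) is not None:
            return pick(direct), step
        via_child = [
            d for i in region if dom_both(i)
            for h, d, _ in tree.edges
            if h == i and sentence.tokens[d].surface in lexicon
        ]
        if pick(via_child) is not None:
            return pick(via_child), step + 1
    return None


def test_key_term_worked_example_is_step3(fig_sentence, lexicon):
    result = find_key_term(fig_sentence, pair_of(fig_sentence), lexicon)
    assert result is not None
    idx, step = result
    assert fig_sentence.tokens[idx].surface == "association"
    assert step == 3


def test_key_term_verb_root_is_step1(lexicon):
    sent = build(
        ["GENO1", "causes", "PHENO1", "."],
        [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")],
        [geno(0), pheno(2)],
    )
    assert find_key_term(sent, pair_of(sent), lexicon) == (1, 1)


def test_key_term_step2_child_of_dominating_word(lexicon):
    # "GENO1 showing association with PHENO1": "showing" dominates both and has
    # lexicon child "association"; "showing" itself is not a relationship term
    words = ["GENO1", "showing", "association", "with", "PHENO1"]
    deps = [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj"),
            (1, 4, "prep_with"), (4, 3, "case")]
    sent = build(words, deps, [geno(0), pheno(4)])
    idx, step = find_key_term(sent, pair_of(sent), lexicon)
    assert (sent.tokens[idx].surface, step) == ("association", 2)


def test_key_term_none_when_no_lexicon_token(lexicon):
    sent = build(
        ["GENO1", "near", "PHENO1"],
        [(-1, 1, "root"), (1, 0, "nn"), (1, 2, "nn")],
        [geno(0), pheno(2)],
    )
    assert find_key_term(sent, pair_of(sent), lexicon) is None


def test_key_term_matches_brute_force_oracle_on_random_trees(lexicon):
    from tests.test_deptree import random_tree

    rng = random.Random(31)
    vocab = ["association", "causes", "patients", "gene", "linked",
             "observed", "correlation", "the", "expression", "with"]
    for _ in range(200):
        n = rng.randint(4, 15)
        tree = random_tree(rng, n)
        words = [rng.choice(vocab) for _ in range(n)]
        spots = rng.sample(range(n), 2)
        gi, pi = min(spots), max(spots)
        words[gi], words[pi] = "GENO1", "PHENO1"
        sent = AnnotatedSentence(
            id="r", tokens=[Token(i, w) for i, w in enumerate(words)],
            entities=[geno(gi), pheno(pi)], deps=tree,
        )
        pair = pair_of(sent)
        assert find_key_term(sent, pair, lexicon) == brute_force_key_term(sent, pair, lexicon)


# ---------------------------------------------------------------------------
# surface and syntactic features
# ---------------------------------------------------------------------------


def _spaced_sentence(gap_left):
    """Lexicon term `gap_left` tokens left of the first entity."""
    words = ["correlation"] + ["filler"] * (gap_left - 1) + ["GENO1", "x", "PHENO1"]
    n = len(words)
    deps = [(-1, 0, "root")] + [(0, i, "dep") for i in range(1, n)]
    return build(words, deps, [geno(n - 3), pheno(n - 1)])


def test_surface_window_inclusive_fourth_token(lexicon):
    sent = _spaced_sentence(4)
    feats = surface_features(sent, pair_of(sent), lexicon)
    assert "surf=correl|before" in feats


def test_surface_window_excludes_fifth_token(lexicon):
    sent = _spaced_sentence(5)
    feats = surface_features(sent, pair_of(sent), lexicon)
    assert not any(f.startswith("surf=correl") for f in feats)


def test_surface_between(lexicon):
    sent = build(
        ["GENO1", "causes", "PHENO1"],
        [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj")],
        [geno(0), pheno(2)],
    )
    feats = surface_features(sent, pair_of(sent), lexicon)
    assert feats == {"surf=cau|between": 1.0}


def test_syntactic_lca_head_relationship_term(lexicon):
    ctree = (
        "(S (NP (NN GENO1)) (VP (VBZ influences) (NP (NN PHENO1))) (. .))"
    )
    sent = build(
        ["GENO1", "influences", "PHENO1", "."],
        [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")],
        [geno(0), pheno(2)], ctree=ctree,
    )
    feats = syntactic_features(sent, pair_of(sent), lexicon)
    assert "synlca=influenc" in feats
    assert "synpath:first=NP|1" in feats


def test_syntactic_lca_head_not_in_lexicon_is_null(lexicon):
    ctree = "(S (NP (NN GENO1)) (VP (VBZ measured) (NP (NN PHENO1))) (. .))"
    sent = build(
        ["GENO1", "measured", "PHENO1", "."],
        [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")],
        [geno(0), pheno(2)], ctree=ctree,
    )
    assert "synlca=NULL" in syntactic_features(sent, pair_of(sent), lexicon)


def test_missing_ctree_sets_flag_only(lexicon):
    sent = build(
        ["GENO1", "causes", "PHENO1"],
        [(-1, 1, "root"), (1, 0, "nsubj"), (1, 2, "dobj")],
        [geno(0), pheno(2)],
    )
    assert syntactic_features(sent, pair_of(sent), lexicon) == {"synlca:noctree": 1.0}


def test_relative_position():
    first = EntityMention("g0", "genotype", 2, 4)
    second = EntityMention("p0", "phenotype", 6, 7)
    assert relative_position(0, first, second) == "before"
    assert relative_position(4, first, second) == "between"
    assert relative_position(3, first, second) == "between"  # inside a mention
    assert relative_position(7, first, second) == "after"


# ---------------------------------------------------------------------------
# full vectors
# ---------------------------------------------------------------------------


def test_worked_example_full_vector(fig_sentence, lexicon):
    feats = extract_features(fig_sentence, pair_of(fig_sentence), lexicon)
    assert "relterm=association" in feats
    assert "relterm:stem=associ" in feats
    assert "collapsed1=of|with" in feats
    assert "collapsed2=of|with" in feats
    assert "neg=false" in feats
    assert "dblbetween=false" in feats


def test_none_sentinel_vector_well_formed(lexicon):
    sent = build(
        ["GENO1", "near", "PHENO1"],
        [(-1, 1, "root"), (1, 0, "nn"), (1, 2, "nn")],
        [geno(0), pheno(2)],
    )
    feats = extract_features(sent, pair_of(sent), lexicon)
    assert "relterm=NONE" in feats
    assert "keyterm=NONE" in feats
    assert all(v == 1.0 for v in feats.values())


def test_extraction_pure_and_family_whitelist(small_corpus, lexicon):
    for sent in small_corpus:
        for pair in candidate_pairs(sent):
            first = extract_features(sent, pair, lexicon)
            second = extract_features(sent, pair, lexicon)
            assert first == second
            for name in first:
                assert feature_family(name) in FEATURE_FAMILIES


def test_etype_swap_changes_only_role_features(lexicon):
    words = ["PHENO1", "is", "associated", "with", "GENO1", "."]
    deps = [(-1, 2, "root"), (2, 0, "nsubjpass"), (2, 1, "auxpass"),
            (2, 4, "prep_with"), (4, 3, "case"), (2, 5, "punct")]
    normal = build(words, deps, [pheno(0), geno(4)])
    # same sentence with the entity types swapped
    swapped = build(words, deps, [geno(0, eid="g0"), pheno(4, eid="p0")])
    f1 = extract_features(normal, pair_of(normal), lexicon)
    f2 = extract_features(swapped, pair_of(swapped), lexicon)
    diff = set(f1) ^ set(f2)
    assert diff  # the grammatical-role feature is etype-anchored
    assert all(name.startswith("relterm:dep=") for name in diff)
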