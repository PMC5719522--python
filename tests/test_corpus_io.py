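"""Corpus serialization, IOB export, lexicon loading, and candidate pairing."""

import json

import pytest

from gprelex.corpus_io import (
    AnnotatedSentence,
    CorpusError,
    EntityMention,
    RelationInstance,
    Token,
    candidate_pairs,
    export_iob,
    load_lexicon,
    read_conllu,
    read_corpus,
    write_corpus,
    write_iob,
)
from gprelex.deptree import DepTree
from gprelex.synthetic_corpus import GeneratorConfig, generate_corpus


def _sentence(n=6, entities=(), sid="s0"):
    tokens = [Token(index=i, surface=f"w{i}") for i in range(n)]
    deps = [(-1, 0, "root")] + [(0, i, "dep") for i in range(1, n)]
    return AnnotatedSentence(
        id=sid, tokens=tokens, entities=list(entities), deps=DepTree(n, deps)
    )


# ---------------------------------------------------------------------------
# round trip and validation
# ---------------------------------------------------------------------------


def test_round_trip_identity(tmp_path, small_corpus):
    path = tmp_path / "corpus.jsonl"
    write_corpus(small_corpus, path)
    back = read_corpus(path)
    assert len(back) == len(small_corpus)
    for a, b in zip(small_corpus, back):
        assert a.id == b.id
        assert a.surfaces == b.surfaces
        assert [t.pos for t in a.tokens] == [t.pos for t in b.tokens]
        assert [(e.id, e.etype, e.start, e.end, e.head) for e in a.entities] == [
            (e.id, e.etype, e.start, e.end, e.head) for e in b.entities
        ]
        assert sorted(a.deps.edges) == sorted(b.deps.edges)
        assert a.ctree.to_bracketed() == b.ctree.to_bracketed()
        assert [(r.key, r.label, r.provenance) for r in a.gold_relations] == [
            (r.key, r.label, r.provenance) for r in b.gold_relations
        ]
    # and a second write is byte-identical
    path2 = tmp_path / "again.jsonl"
    write_corpus(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_span_end_beyond_token_count_rejected():
    with pytest.raises(CorpusError, match="beyond"):
        _sentence(4, entities=[EntityMention("g0", "genotype", 2, 5)])


def test_overlapping_spans_rejected():
    ents = [
        EntityMention("g0", "genotype", 1, 3),
        EntityMention("p0", "phenotype", 2, 4),
    ]
    with pytest.raises(CorpusError, match="overlap"):
        _sentence(6, entities=ents)


def test_malformed_record_names_line(tmp_path):
    path = tmp_path / "bad.jsonl"
    path.write_text('{"id": "a", "tokens": [{"surface": "x"}], "entities": []}\nnot json\n')
    with pytest.raises(CorpusError, match="line 2"):
        read_corpus(path)


def test_duplicate_sentence_ids_rejected(tmp_path, small_corpus):
    path = tmp_path / "dup.jsonl"
    write_corpus([small_corpus[0], small_corpus[0]], path)
    with pytest.raises(CorpusError, match="duplicate sentence id"):
        read_corpus(path)


def test_generated_fixture_counts():
    corpus = generate_corpus(GeneratorConfig(n_sentences=5, seed=1))
    assert len(corpus) == 5
    assert all(s.gold_relations for s in corpus)


def test_confidence_provenance_coupling():
    with pytest.raises(CorpusError):
        RelationInstance("s", "g", "p", label="positive", provenance="model")
    with pytest.raises(CorpusError):
        RelationInstance("s", "g", "p", label="positive", confidence=0.9, provenance="gold")
    ok = RelationInstance("s", "g", "p", label="positive", confidence=0.9, provenance="model")
    assert ok.confidence == 0.9


# ---------------------------------------------------------------------------
# IOB export
# ---------------------------------------------------------------------------


def _decode_iob(rows):
    """Independent IOB decoder: tag stream back to (etype, start, end) spans."""
    spans = []
    start = None
    etype = None
    for i, (_tok, tag) in enumerate(rows + [("", "O")]):
        if tag.startswith("B-") or tag == "O":
            if start is not None:
                spans.append((etype, start, i))
                start, etype = None, None
        if tag.startswith("B-"):
            start, etype = i, tag[2:].lower()
    return spans


def test_iob_tags_single_span():
    sent = _sentence(6, entities=[EntityMention("g0", "genotype", 3, 5)])
    rows = export_iob([sent])[0]
    assert [tag for _, tag in rows] == ["O", "O", "O", "B-GENOTYPE", "I-GENOTYPE", "O"]


def test_iob_no_entities_all_outside():
    rows = export_iob([_sentence(4)])[0]
    assert [tag for _, tag in rows] == ["O"] * 4


def test_iob_adjacent_mentions_restart_with_b():
    ents = [
        EntityMention("g0", "genotype", 1, 3),
        EntityMention("g1", "genotype", 3, 4),
    ]
    rows = export_iob([_sentence(6, entities=ents)])[0]
    assert [tag for _, tag in rows] == ["O", "B-GENOTYPE", "I-GENOTYPE", "B-GENOTYPE", "O", "O"]


def test_iob_round_trip_recovers_spans(small_corpus):
    for sent, rows in zip(small_corpus, export_iob(small_corpus)):
        assert len(rows) == len(sent.tokens)
        expected = sorted((e.etype, e.start, e.end) for e in sent.entities)
        assert sorted(_decode_iob(rows)) == expected


def test_write_iob_tsv(tmp_path, small_corpus):
    path = tmp_path / "out.iob"
    write_iob(small_corpus[:2], path)
    lines = path.read_text().splitlines()
    assert lines[0].count("\t") == 1


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


def test_load_lexicon_stems(tmp_path):
    path = tmp_path / "lex.txt"
    path.write_text("associated\ncorrelation\n")
    lex = load_lexicon(path)
    assert len(lex) == 2
    assert lex.contains_stem("associ")
    assert lex.contains_stem("correl")


def test_lexicon_duplicates_deduplicated(tmp_path):
    path = tmp_path / "lex.txt"
    path.write_text("associated\nassociated\n\n# comment\n")
    assert len(load_lexicon(path)) == 1


def test_lexicon_lookup_case_insensitive(lexicon):
    assert "Associated" in lexicon
    assert "ASSOCIATION" in lexicon
    assert "sequenced" not in lexicon


def test_empty_lexicon_is_configuration_error(tmp_path):
    path = tmp_path / "lex.txt"
    path.write_text("# only a comment\n\n")
    with pytest.raises(CorpusError, match="empty effective lexicon"):
        load_lexicon(path)


def test_lexicon_categories(lexicon):
    assert lexicon.lookup("in").category == "preposition"
    assert lexicon.lookup("association").category in ("noun", "verb")


# ---------------------------------------------------------------------------
# candidate pairs
# ---------------------------------------------------------------------------


def test_single_pair():
    ents = [
        EntityMention("g0", "genotype", 0, 1),
        EntityMention("p0", "phenotype", 2, 3),
    ]
    assert len(candidate_pairs(_sentence(4, entities=ents))) == 1


def test_only_genotypes_yields_no_pairs():
    ents = [EntityMention("g0", "genotype", 0, 1), EntityMention("g1", "genotype", 2, 3)]
    assert candidate_pairs(_sentence(4, entities=ents)) == []


def test_pair_count_is_product():
    ents = [
        EntityMention("g0", "genotype", 0, 1),
        EntityMention("g1", "genotype", 1, 2),
        EntityMention("p0", "phenotype", 2, 3),
        EntityMention("p1", "phenotype", 3, 4),
        EntityMention("p2", "phenotype", 4, 5),
    ]
    pairs = candidate_pairs(_sentence(6, entities=ents))
    assert len(pairs) == 6
    assert len({p.key for p in pairs}) == 6
    assert all(p.label == "unknown" for p in pairs)


def test_pair_count_product_on_random_corpus():
    corpus = generate_corpus(GeneratorConfig(n_sentences=200, seed=13))
    for sent in corpus:
        n_g = len(sent.mentions("genotype"))
        n_p = len(sent.mentions("phenotype"))
        assert len(candidate_pairs(sent)) == n_g * n_p


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

CONLLU = """\
# sent_id = ex1
1\tAnemia\tanemia\tNOUN\tNN\t_\t4\tnsubj:pass\t_\t_
2\tis\tbe\tAUX\tVBZ\t_\t4\taux:pass\t_\t_
3\tstrongly\tstrongly\tADV\tRB\t_\t4\tadvmod\t_\t_
4\tassociated\tassociate\tVERB\tVBN\t_\t0\troot\t_\t_
5\twith\twith\tADP\tIN\t_\t6\tcase\t_\t_
6\tHBB\thbb\tPROPN\tNNP\t_\t4\tobl\t_\t_
"""

ANN = "E\tex1\tp0\tphenotype\t0\t1\nE\tex1\tg0\tgenotype\t5\t6\nR\tex1\tg0\tp0\tpositive\n"


def test_conllu_collapses_prepositions(tmp_path):
    path = tmp_path / "ex.conllu"
    path.write_text(CONLLU)
    (tmp_path / "ex.conllu.ann").write_text(ANN)
    [sent] = read_corpus(path, format="conllu+ann")
    assert sent.id == "ex1"
    labels = {l for _, _, l in sent.deps.edges}
    assert "prep_with" in labels  # obl + case child collapsed
    assert "nsubjpass" in labels
    assert [e.id for e in sent.entities] == ["p0", "g0"]
    assert sent.gold_relations[0].label == "positive"


def test_conllu_unmappable_labels_pass_through(tmp_path):
    text = CONLLU.replace("advmod", "weirdrel")
    path = tmp_path / "ex.conllu"
    path.write_text(text)
    [sent] = read_conllu(path)
    assert any(l == "weirdrel" for _, _, l in sent.deps.edges)
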