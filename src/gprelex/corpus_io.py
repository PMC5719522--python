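"""Corpus, lexicon, and annotation I/O.

The native corpus format is JSON-lines: one annotated sentence per line with
explicit token, entity, dependency-edge, optional bracketed constituency, and
gold-relation fields.  A minimal CoNLL-U reader is provided for dependency
parses produced elsewhere; its labels are mapped to the collapsed-preposition
Stanford dialect where possible (``nmod``/``obl`` + ``case`` child becomes
``prep_<word>``, ``conj`` + ``cc`` becomes ``conj_<word>``) and passed through
verbatim otherwise.  Entity spans use 0-based half-open token intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from gprelex.deptree import ConstTree, DepTree, validate_tree
from gprelex.stemming import stem

ENTITY_TYPES = ("genotype", "phenotype")
LABELS = ("positive", "negative", "unknown")
PROVENANCES = ("gold", "rule", "model", "agreement", "selftrain", "candidate")

P_PREPOSITIONS = frozenset(
    {"of", "by", "to", "on", "for", "in", "through", "with"}
)  # the preposition set of the preposition-linked pattern
P4_PREPOSITIONS = P_PREPOSITIONS | {"between"}


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus records."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    pos: Optional[str] = None
    stem: Optional[str] = None


@dataclass(frozen=True)
class EntityMention:
    """An entity span; ``head_index`` anchors it in the dependency tree."""

    id: str
    etype: str
    start: int
    end: int
    head_index: int = -1  # -1 means "default to the last span token"

    def __post_init__(self):
        if self.etype not in ENTITY_TYPES:
            raise CorpusError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(f"bad span [{self.start}, {self.end}) for {self.id}")
        head = self.head
        if not (self.start <= head < self.end):
            raise CorpusError(f"head_index {head} outside span of {self.id}")

    @property
    def head(self) -> int:
        return self.end - 1 if self.head_index < 0 else self.head_index

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RelationInstance:
    """One (genotype mention, phenotype mention) candidate within a sentence."""

    sentence_id: str
    geno_id: str
    pheno_id: str
    label: str = "unknown"
    confidence: Optional[float] = None
    provenance: str = "gold"

    def __post_init__(self):
        if self.label not in LABELS:
            raise CorpusError(f"unknown label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise CorpusError(f"unknown provenance {self.provenance!r}")
        has_conf = self.confidence is not None
        needs_conf = self.provenance in ("model", "selftrain")
        if has_conf != needs_conf:
            raise CorpusError(
                f"confidence must be present iff provenance is model/selftrain "
                f"(got provenance={self.provenance}, confidence={self.confidence})"
            )
        if has_conf and not (0.0 <= self.confidence <= 1.0):
            raise CorpusError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sentence_id, self.geno_id, self.pheno_id)


@dataclass
class AnnotatedSentence:
    id: str
    tokens: list[Token]
    entities: list[EntityMention] = field(default_factory=list)
    deps: Optional[DepTree] = None
    ctree: Optional[ConstTree] = None
    gold_relations: list[RelationInstance] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise CorpusError(f"{self.id}: token indices not contiguous at {i}")
            if not tok.surface:
                raise CorpusError(f"{self.id}: empty token surface at {i}")
        seen_ids = set()
        occupied: set[int] = set()
        for ent in self.entities:
            if ent.id in seen_ids:
                raise CorpusError(f"{self.id}: duplicate entity id {ent.id}")
            seen_ids.add(ent.id)
            if ent.end > n:
                raise CorpusError(
                    f"{self.id}: entity {ent.id} span end {ent.end} beyond {n} tokens"
                )
            span = set(range(ent.start, ent.end))
            if span & occupied:
                raise CorpusError(f"{self.id}: entity {ent.id} overlaps another span")
            occupied |= span
        if self.deps is not None:
            if self.deps.n_tokens != n:
                raise CorpusError(f"{self.id}: dependency tree covers {self.deps.n_tokens} tokens, sentence has {n}")
            validate_tree(self.deps)
        by_id = {e.id: e for e in self.entities}
        for rel in self.gold_relations:
            for eid, etype in ((rel.geno_id, "genotype"), (rel.pheno_id, "phenotype")):
                if eid not in by_id:
                    raise CorpusError(f"{self.id}: relation references unknown entity {eid}")
                if by_id[eid].etype != etype:
                    raise CorpusError(
                        f"{self.id}: relation expects a {etype} but {eid} is {by_id[eid].etype}"
                    )

    def mentions(self, etype: str) -> list[EntityMention]:
        return sorted(
            (e for e in self.entities if e.etype == etype),
            key=lambda e: (e.start, e.id),
        )

    def entity(self, eid: str) -> EntityMention:
        for e in self.entities:
            if e.id == eid:
                return e
        raise CorpusError(f"{self.id}: no entity {eid}")

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconEntry:
    lemma: str
    stem: str
    surface_forms: frozenset[str]
    category: str  # verb | noun | preposition


_NOUN_SUFFIXES = ("ion", "ment", "ance", "ence", "ity", "ship", "age", "ility")


def _infer_category(term: str) -> str:
    if term in P4_PREPOSITIONS:
        return "preposition"
    if term.endswith(_NOUN_SUFFIXES) or term in ("risk", "role"):
        return "noun"
    return "verb"


class Lexicon:
    """Relationship-term lexicon with case-insensitive, stem-based lookup."""

    def __init__(self, terms: Iterable[tuple[str, Optional[str]]]):
        grouped: dict[str, dict] = {}
        for surface, category in terms:
            surface = surface.strip().lower()
            if not surface:
                continue
            s = stem(surface)
            g = grouped.setdefault(s, {"surfaces": set(), "category": None, "lemma": surface})
            g["surfaces"].add(surface)
            if len(surface) < len(g["lemma"]):
                g["lemma"] = surface
            if category:
                g["category"] = category
        if not grouped:
            raise CorpusError("configuration error: empty effective lexicon")
        self.entries: dict[str, LexiconEntry] = {
            s: LexiconEntry(
                lemma=g["lemma"],
                stem=s,
                surface_forms=frozenset(g["surfaces"]),
                category=g["category"] or _infer_category(g["lemma"]),
            )
            for s, g in sorted(grouped.items())
        }
        self._surfaces = {surf for e in self.entries.values() for surf in e.surface_forms}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        w = word.lower()
        return w in self._surfaces or stem(w) in self.entries

    def contains_stem(self, s: str) -> bool:
        return s in self.entries

    def lookup(self, word: str) -> Optional[LexiconEntry]:
        return self.entries.get(stem(word.lower()))


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon file: one term per line, ``#`` comments and blanks ignored.

    An optional second tab-separated column gives the category
    (verb | noun | preposition).
    """
    terms: list[tuple[str, Optional[str]]] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        category = parts[1].strip().lower() if len(parts) > 1 else None
        terms.append((parts[0], category))
    return Lexicon(terms)


def default_lexicon() -> Lexicon:
    """The bundled genotype-phenotype relationship-term lexicon."""
    ref = resources.files("gprelex").joinpath("data/lexicon.txt")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


# ---------------------------------------------------------------------------
# candidate pairs and IOB export
# ---------------------------------------------------------------------------


def candidate_pairs(sentence: AnnotatedSentence) -> list[RelationInstance]:
    """One unknown-labelled instance per (genotype, phenotype) mention pair."""
    out = []
    for g in sentence.mentions("genotype"):
        for p in sentence.mentions("phenotype"):
            out.append(
                RelationInstance(
                    sentence_id=sentence.id,
                    geno_id=g.id,
                    pheno_id=p.id,
                    label="unknown",
                    provenance="candidate",
                )
            )
    return out


def export_iob(corpus: Sequence[AnnotatedSentence]) -> list[list[tuple[str, str]]]:
    """Per-sentence (token, IOB tag) pairs; tags are B-/I-<ETYPE> or O."""
    out = []
    for sent in corpus:
        tags = ["O"] * len(sent.tokens)
        for ent in sent.entities:
            suffix = ent.etype.upper()
            tags[ent.start] = f"B-{suffix}"
            for i in range(ent.start + 1, ent.end):
                tags[i] = f"I-{suffix}"
        out.append(list(zip(sent.surfaces, tags)))
    return out


def write_iob(corpus: Sequence[AnnotatedSentence], path: str | Path) -> None:
    """Two-column TSV, sentences separated by blank lines."""
    lines = []
    for sent_rows in export_iob(corpus):
        lines.extend(f"{tok}\t{tag}" for tok, tag in sent_rows)
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON-lines serialization
# ---------------------------------------------------------------------------


def _sentence_to_record(sent: AnnotatedSentence) -> dict:
    rec = {
        "id": sent.id,
        "tokens": [
            {"surface": t.surface, **({"pos": t.pos} if t.pos else {})}
            for t in sent.tokens
        ],
        "entities": [
            {
                "id": e.id,
                "etype": e.etype,
                "start": e.start,
                "end": e.end,
                "head": e.head,
            }
            for e in sent.entities
        ],
        "deps": [[h, d, l] for h, d, l in sent.deps.edges] if sent.deps else None,
        "ctree": sent.ctree.to_bracketed() if sent.ctree else None,
        "relations": [
            {
                "geno": r.geno_id,
                "pheno": r.pheno_id,
                "label": r.label,
                "provenance": r.provenance,
                **({"confidence": r.confidence} if r.confidence is not None else {}),
            }
            for r in sent.gold_relations
        ],
    }
    return rec


def _sentence_from_record(rec: dict, lineno: int) -> AnnotatedSentence:
    try:
        tokens = [
            Token(index=i, surface=t["surface"], pos=t.get("pos"))
            for i, t in enumerate(rec["tokens"])
        ]
        entities = [
            EntityMention(
                id=e["id"],
                etype=e["etype"],
                start=e["start"],
                end=e["end"],
                head_index=e.get("head", -1),
            )
            for e in rec["entities"]
        ]
        deps = DepTree(len(tokens), rec["deps"]) if rec.get("deps") else None
        ctree = ConstTree.from_bracketed(rec["ctree"]) if rec.get("ctree") else None
        relations = [
            RelationInstance(
                sentence_id=rec["id"],
                geno_id=r["geno"],
                pheno_id=r["pheno"],
                label=r.get("label", "unknown"),
                confidence=r.get("confidence"),
                provenance=r.get("provenance", "gold"),
            )
            for r in rec.get("relations", [])
        ]
        return AnnotatedSentence(
            id=rec["id"], tokens=tokens, entities=entities,
            deps=deps, ctree=ctree, gold_relations=relations,
        )
    except (KeyError, TypeError) as exc:
        raise CorpusError(f"parse error at line {lineno}: {exc!r}") from exc


def write_corpus(corpus: Sequence[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            fh.write(json.dumps(_sentence_to_record(sent), ensure_ascii=False) + "\n")


def read_corpus(path: str | Path, format: str = "jsonl") -> list[AnnotatedSentence]:
    """Read a corpus in the ``jsonl`` native format or ``conllu+ann``."""
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "conllu+ann":
        return read_conllu(path, ann_path=str(path) + ".ann")
    raise CorpusError(f"unknown corpus format {format!r}")


def _read_jsonl(path: str | Path) -> list[AnnotatedSentence]:
    sentences = []
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"parse error at line {lineno}: {exc}") from exc
            sent = _sentence_from_record(rec, lineno)
            if sent.id in ids:
                raise CorpusError(f"duplicate sentence id {sent.id} at line {lineno}")
            ids.add(sent.id)
            sentences.append(sent)
    return sentences


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------


def _collapse_conllu(rows: list[dict]) -> list[tuple[int, int, str]]:
    """Map CoNLL-U basic relations onto the collapsed Stanford dialect.

    ``nmod``/``obl`` dependents that have a ``case`` child collapse to
    ``prep_<case word>``; ``conj`` dependents with a ``cc`` child collapse to
    ``conj_<cc word>``; anything unmappable passes through verbatim.
    """
    case_of: dict[int, str] = {}
    cc_of: dict[int, str] = {}
    for r in rows:
        if r["deprel"] == "case":
            case_of[r["head"]] = r["form"].lower()
        elif r["deprel"] == "cc":
            cc_of[r["head"]] = r["form"].lower()
    edges = []
    for r in rows:
        label = r["deprel"]
        base = label.split(":")[0]
        if base in ("nmod", "obl") and r["id"] in case_of:
            label = f"prep_{case_of[r['id']]}"
        elif base == "conj" and r["id"] in cc_of:
            label = f"conj_{cc_of[r['id']]}"
        elif base == "nsubj" and label.endswith(":pass"):
            label = "nsubjpass"
        edges.append((r["head"] - 1, r["id"] - 1, label))
    return edges


def read_conllu(path: str | Path, ann_path: Optional[str | Path] = None) -> list[AnnotatedSentence]:
    """Read sentences from a CoNLL-U file, with entities/relations from a
    companion ``.ann`` file when present.

    The ``.ann`` format is line-based and tab-separated:
    ``E<TAB>sent_id<TAB>entity_id<TAB>etype<TAB>start<TAB>end[<TAB>head]`` and
    ``R<TAB>sent_id<TAB>geno_id<TAB>pheno_id<TAB>label``.
    """
    ents: dict[str, list[EntityMention]] = {}
    rels: dict[str, list[tuple[str, str, str]]] = {}
    if ann_path is not None and Path(ann_path).exists():
        for lineno, raw in enumerate(Path(ann_path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "E" and len(parts) >= 6:
                head = int(parts[6]) if len(parts) > 6 else -1
                ents.setdefault(parts[1], []).append(
                    EntityMention(parts[2], parts[3], int(parts[4]), int(parts[5]), head)
                )
            elif parts[0] == "R" and len(parts) >= 5:
                rels.setdefault(parts[1], []).append((parts[2], parts[3], parts[4]))
            else:
                raise CorpusError(f"parse error at line {lineno} of {ann_path}")

    sentences = []
    rows: list[dict] = []
    sent_id: Optional[str] = None
    counter = 0

    def flush():
        nonlocal rows, sent_id, counter
        if not rows:
            return
        sid = sent_id or f"conllu_{counter}"
        tokens = [
            Token(index=i, surface=r["form"], pos=r["xpos"] or r["upos"])
            for i, r in enumerate(rows)
        ]
        tree = DepTree(len(rows), _collapse_conllu(rows))
        relations = [
            RelationInstance(sid, g, p, label=l, provenance="gold")
            for g, p, l in rels.get(sid, [])
        ]
        sentences.append(
            AnnotatedSentence(
                id=sid, tokens=tokens, entities=ents.get(sid, []),
                deps=tree, gold_relations=relations,
            )
        )
        rows, sent_id = [], None
        counter += 1

    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if line.startswith("#"):
            if line[1:].strip().startswith("sent_id"):
                sent_id = line.split("=", 1)[1].strip()
            continue
        if not line.strip():
            flush()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise CorpusError(f"parse error at line {lineno}: expected 10 columns")
        if "-" in cols[0] or "." in cols[0]:
            continue  # skip multiword-token and empty-node rows
        rows.append(
            {
                "id": int(cols[0]),
                "form": cols[1],
                "upos": None if cols[3] == "_" else cols[3],
                "xpos": None if cols[4] == "_" else cols[4],
                "head": int(cols[6]),
                "deprel": cols[7],
            }
        )
    flush()
    return sentences
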