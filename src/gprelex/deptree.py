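"""Dependency- and constituency-tree structures and traversals.

Dependency trees use the collapsed-preposition Stanford label dialect
(``nsubj``, ``nsubjpass``, ``prep_of``, ``prep_with``, ``rcmod``, ``neg``,
...).  The root token's head index is ``-1``.  Because collapsed output
absorbs preposition tokens into edge labels, fixture trees attach the absorbed
function words back to the graph (conventionally with a ``case`` or ``cc``
edge) so that every tree is a single-rooted spanning tree over the tokens.

Constituency trees are Penn-style bracketed trees over the token leaves, with
a small Collins-style head-percolation table for the common phrase labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


class TreeError(ValueError):
    """Raised for malformed dependency or constituency trees."""


# ---------------------------------------------------------------------------
# dependency trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepTree:
    """A single-rooted dependency tree over ``n_tokens`` tokens.

    ``edges`` are ``(head, dependent, label)`` triples with ``head == -1``
    marking the root edge.  Validation is explicit via :func:`validate_tree`.
    """

    n_tokens: int
    edges: tuple[tuple[int, int, str], ...]

    def __init__(self, n_tokens: int, edges: Sequence[Sequence]) -> None:
        object.__setattr__(self, "n_tokens", int(n_tokens))
        object.__setattr__(
            self, "edges", tuple((int(h), int(d), str(l)) for h, d, l in edges)
        )

    def parents(self) -> dict[int, tuple[int, str]]:
        """Map dependent -> (head, label); raises on a multi-headed token."""
        out: dict[int, tuple[int, str]] = {}
        for h, d, l in self.edges:
            if d in out:
                raise TreeError(f"multi-headed: token {d} has two heads")
            out[d] = (h, l)
        return out

    @property
    def root(self) -> int:
        parents = self.parents()
        roots = [t for t in range(self.n_tokens) if t not in parents or parents[t][0] == -1]
        if len(roots) != 1:
            raise TreeError(f"forest not tree: {len(roots)} root candidates")
        return roots[0]

    def children(self, token: int) -> list[tuple[int, str]]:
        return [(d, l) for h, d, l in self.edges if h == token]

    def head_chain(self, token: int) -> list[int]:
        """Tokens from ``token`` up to (and including) the root."""
        parents = self.parents()
        chain = [token]
        seen = {token}
        cur = token
        while cur in parents and parents[cur][0] != -1:
            cur = parents[cur][0]
            if cur in seen:
                raise TreeError("cyclic dependency")
            seen.add(cur)
            chain.append(cur)
        return chain


def validate_tree(tree: DepTree) -> None:
    """Check the single-head, acyclicity, and connectivity invariants.

    Raises :class:`TreeError` with a message naming the violation
    ("multi-headed", "cyclic dependency", "forest not tree").
    """
    parents = tree.parents()  # raises on multi-headed tokens
    for h, d, _ in tree.edges:
        if not (0 <= d < tree.n_tokens) or not (-1 <= h < tree.n_tokens):
            raise TreeError(f"edge ({h}, {d}) out of token range")
    roots = [t for t in range(tree.n_tokens) if t not in parents or parents[t][0] == -1]
    # Walk every parent chain; a revisit within one walk is a cycle.
    for t in range(tree.n_tokens):
        seen = {t}
        cur = t
        while cur in parents and parents[cur][0] != -1:
            cur = parents[cur][0]
            if cur in seen:
                raise TreeError("cyclic dependency")
            seen.add(cur)
    if len(roots) != 1:
        raise TreeError(f"forest not tree: {len(roots)} root candidates")


@dataclass(frozen=True)
class DepPath:
    """The unique tree path between two tokens.

    ``nodes`` runs from the first endpoint to the second; ``labels`` has one
    ``(label, direction)`` entry per step, direction ``"up"`` when the step
    moves toward a head and ``"down"`` toward a dependent.  ``root_pos`` is the
    index in ``nodes`` of the path root -- the unique highest node on the path.
    """

    nodes: tuple[int, ...]
    labels: tuple[tuple[str, str], ...]
    root_pos: int

    @property
    def path_root(self) -> int:
        return self.nodes[self.root_pos]

    @property
    def label_names(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.labels)

    def reverse(self) -> "DepPath":
        flipped = tuple(
            (l, "up" if d == "down" else "down") for l, d in reversed(self.labels)
        )
        return DepPath(tuple(reversed(self.nodes)), flipped, len(self.nodes) - 1 - self.root_pos)

    def to_string(self, surfaces: Sequence[str]) -> str:
        """Render as ``word-label-word-...-word`` over token surfaces."""
        parts = [surfaces[self.nodes[0]]]
        for (label, _), node in zip(self.labels, self.nodes[1:]):
            parts.append(label)
            parts.append(surfaces[node])
        return "-".join(parts)


def dependency_path(tree: DepTree, a: int, b: int) -> DepPath:
    """Path from token ``a`` to token ``b``; raises on a degenerate pair."""
    if a == b:
        raise TreeError(f"degenerate pair: both endpoints are token {a}")
    parents = tree.parents()
    chain_a = tree.head_chain(a)
    chain_b = tree.head_chain(b)
    on_b = {t: i for i, t in enumerate(chain_b)}
    for ia, t in enumerate(chain_a):
        if t in on_b:
            lca, ib = t, on_b[t]
            break
    else:  # pragma: no cover - unreachable on a validated tree
        raise TreeError("forest not tree: endpoints are disconnected")
    nodes = chain_a[: ia + 1] + list(reversed(chain_b[:ib]))
    labels: list[tuple[str, str]] = []
    for t in chain_a[:ia]:
        labels.append((parents[t][1], "up"))
    for t in reversed(chain_b[:ib]):
        labels.append((parents[t][1], "down"))
    return DepPath(tuple(nodes), tuple(labels), ia)


def dominates(tree: DepTree, a: int, b: int) -> bool:
    """True iff ``a`` is a proper ancestor of ``b`` (head-to-dependent)."""
    if a == b:
        return False
    return a in tree.head_chain(b)[1:]


def dominates_or_self(tree: DepTree, a: int, b: int) -> bool:
    return a == b or dominates(tree, a, b)


# ---------------------------------------------------------------------------
# constituency trees
# ---------------------------------------------------------------------------


@dataclass
class ConstNode:
    label: str
    children: list["ConstNode"] = field(default_factory=list)
    word: Optional[str] = None  # set on leaves only
    token_index: int = -1  # set on leaves only
    head_child: Optional[int] = None  # explicit override of the head table

    @property
    def is_leaf(self) -> bool:
        return self.word is not None

    def leaves(self) -> Iterator["ConstNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    @property
    def span(self) -> tuple[int, int]:
        """Covered token interval, half-open."""
        idx = [l.token_index for l in self.leaves()]
        return (min(idx), max(idx) + 1)


# Collins-style head-finding table: label -> (scan direction, priority list).
# Fixture-scale subset; unknown labels fall back to the leftmost child.
HEAD_RULES: dict[str, tuple[str, tuple[str, ...]]] = {
    "S": ("left", ("VP", "S", "SBAR", "ADJP", "UCP", "NP")),
    "SBAR": ("left", ("S", "SQ", "SINV", "SBAR", "FRAG")),
    "VP": ("left", ("VBD", "VBN", "MD", "VBZ", "VB", "VBG", "VBP", "VP", "ADJP", "NN", "NNS", "NP")),
    "NP": ("right", ("NN", "NNP", "NNPS", "NNS", "NX", "POS", "JJR", "NP")),
    "PP": ("left", ("IN", "TO", "VBG", "VBN", "RP", "FW")),
    "ADJP": ("right", ("NNS", "NN", "JJ", "VBN", "VBG", "ADJP", "JJR")),
    "ADVP": ("right", ("RB", "RBR", "RBS", "FW", "ADVP", "TO", "CD")),
}


class ConstTree:
    """A Penn-style constituency tree over token leaves."""

    def __init__(self, root: ConstNode):
        self.root = root
        leaves = list(root.leaves())
        idx = [l.token_index for l in leaves]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise TreeError("constituency leaves out of token order")
        self.n_leaves = len(leaves)

    @classmethod
    def from_bracketed(cls, text: str) -> "ConstTree":
        """Parse a bracketed string like ``(S (NP (DT The) (NN gene)) ...)``."""
        tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        pos = 0
        counter = [0]

        def parse() -> ConstNode:
            nonlocal pos
            if tokens[pos] != "(":
                raise TreeError(f"malformed bracketing near token {pos}")
            pos += 1
            label = tokens[pos]
            pos += 1
            node = ConstNode(label)
            while tokens[pos] != ")":
                if tokens[pos] == "(":
                    node.children.append(parse())
                else:
                    node.word = tokens[pos]
                    node.token_index = counter[0]
                    counter[0] += 1
                    pos += 1
            pos += 1
            if not node.children and node.word is None:
                raise TreeError(f"empty constituent {label}")
            return node

        root = parse()
        if pos != len(tokens):
            raise TreeError("trailing material after bracketed tree")
        return cls(root)

    def to_bracketed(self) -> str:
        def render(n: ConstNode) -> str:
            if n.is_leaf:
                return f"({n.label} {n.word})"
            return "(" + n.label + " " + " ".join(render(c) for c in n.children) + ")"

        return render(self.root)

    # -- traversals ---------------------------------------------------------

    def covering_node(self, span: tuple[int, int]) -> ConstNode:
        """Deepest node whose yield covers the half-open token ``span``."""
        start, end = span
        s, e = self.root.span
        if not (s <= start and end <= e):
            raise TreeError(f"span {span} outside tree yield {(s, e)}")
        node = self.root
        while True:
            for child in node.children:
                cs, ce = child.span
                if cs <= start and end <= ce:
                    node = child
                    break
            else:
                return node

    def head_word(self, node: ConstNode) -> str:
        """Lexical head of ``node`` via the head table (or explicit override)."""
        while not node.is_leaf:
            if node.head_child is not None:
                node = node.children[node.head_child]
                continue
            rule = HEAD_RULES.get(node.label)
            chosen = None
            if rule is not None:
                direction, priorities = rule
                order = node.children if direction == "left" else list(reversed(node.children))
                for wanted in priorities:
                    for child in order:
                        if child.label == wanted:
                            chosen = child
                            break
                    if chosen is not None:
                        break
            node = chosen if chosen is not None else node.children[0]
        assert node.word is not None
        return node.word


def const_lca_head(ctree: ConstTree, span1: tuple[int, int], span2: tuple[int, int]) -> tuple[str, str]:
    """Label and lexical head of the lowest node dominating both spans."""
    lo = min(span1[0], span2[0])
    hi = max(span1[1], span2[1])
    lca = ctree.covering_node((lo, hi))
    return lca.label, ctree.head_word(lca)


def const_lca(ctree: ConstTree, span1: tuple[int, int], span2: tuple[int, int]) -> ConstNode:
    lo = min(span1[0], span2[0])
    hi = max(span1[1], span2[1])
    return ctree.covering_node((lo, hi))


def path_to_lca(ctree: ConstTree, span: tuple[int, int], lca: ConstNode) -> list[tuple[str, int]]:
    """Constituent labels from the LCA's child down to the entity's minimal
    covering constituent, paired with distance 1, 2, ... from the LCA.

    Empty when the span equals the LCA's own yield.
    """
    s, e = lca.span
    if not (s <= span[0] and span[1] <= e):
        raise TreeError(f"LCA does not dominate span {span}")
    if (span[0], span[1]) == (s, e):
        return []
    out: list[tuple[str, int]] = []
    node = lca
    dist = 0
    while True:
        for child in node.children:
            cs, ce = child.span
            if cs <= span[0] and span[1] <= ce:
                dist += 1
                out.append((child.label, dist))
                node = child
                break
        else:
            return out
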