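"""Sentence-level syntactic analyses behind a pluggable backend contract.

The feature scheme needs, per sentence: tokens with lemma and POS, a
dependency graph, and a constituency tree.  Any tokenizer + tagger +
parser stack can provide these by satisfying :class:`ParserBackend`; the
test bed and the synthetic corpus use :class:`FixtureBackend`, which
serves parses constructed alongside the sentences themselves, so results
are deterministic and no parsing model is required at run time.

On top of the parse objects this module provides the tree/graph
primitives the features consume:

* proper *dominance* between constituents;
* the Langacker *command* relation, generalised over a category C: a node
  X C-commands Y iff neither dominates the other and the lowest C-labelled
  ancestor of X also dominates Y (S-, VP- and NP-command);
* shortest undirected *dependency paths* with labels in traversal order;
* the syntactic *scope* of a negation cue, taken as the contiguous token
  range from the cue to the right edge of the smallest clause (S-category
  constituent) dominating it — the dominant convention in the scope
  detection literature.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .cue_lexicon import CueMatch
from .errors import AlignmentError, BackendError, MissingFixtureError


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    lemma: str
    pos: str
    start: Optional[int] = None  # char offset within the sentence, when known

    def as_triple(self) -> tuple[str, str, str]:
        return (self.text, self.lemma, self.pos)


@dataclass(frozen=True)
class DepEdge:
    head: int
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if self.head == self.dependent:
            raise ValueError("self-loop dependency edge")


class ConstNode:
    """A constituency-tree node covering the token span [start, end)."""

    __slots__ = ("label", "start", "end", "children", "parent")

    def __init__(self, label: str, start: int, end: int,
                 children: Optional[list["ConstNode"]] = None):
        self.label = label
        self.start = start
        self.end = end
        self.children: list[ConstNode] = children or []
        self.parent: Optional[ConstNode] = None
        for ch in self.children:
            ch.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaves(self) -> list["ConstNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ConstNode({self.label}, [{self.start},{self.end}))"


@dataclass
class ParseResult:
    tokens: list[Token]
    dep_edges: list[DepEdge]
    tree: ConstNode
    connected: bool = True  # backend capability: dep graph is connected

    def __post_init__(self) -> None:
        leaves = self.tree.leaves()
        if len(leaves) != len(self.tokens):
            raise ValueError("tree yield does not match token count")
        for leaf, tok in zip(leaves, self.tokens):
            if leaf.start != tok.index:
                raise ValueError("tree yield out of order with tokens")
        for e in self.dep_edges:
            if not (0 <= e.head < len(self.tokens) and 0 <= e.dependent < len(self.tokens)):
                raise ValueError("dependency edge index out of range")

    def leaf_of(self, token_index: int) -> ConstNode:
        return self.tree.leaves()[token_index]

    def triples(self) -> list[tuple[str, str, str]]:
        return [t.as_triple() for t in self.tokens]


class ParserBackend(Protocol):
    """Anything that turns a sentence string into a :class:`ParseResult`."""

    def parse(self, sentence_text: str) -> ParseResult: ...


class FixtureBackend:
    """Serves pre-computed parses keyed by exact sentence text.

    A missing sentence raises :class:`MissingFixtureError` — never a
    silent fallback to some degraded analysis.
    """

    def __init__(self, records: Optional[dict[str, ParseResult]] = None):
        self._records: dict[str, ParseResult] = dict(records or {})

    def add(self, sentence_text: str, result: ParseResult) -> None:
        self._records[sentence_text] = result

    def parse(self, sentence_text: str) -> ParseResult:
        try:
            return self._records[sentence_text]
        except KeyError:
            raise MissingFixtureError(
                f"no fixture parse for sentence: {sentence_text[:60]!r}"
            ) from None

    def to_dict(self) -> dict:
        return {text: parse_to_dict(p) for text, p in sorted(self._records.items())}

    @classmethod
    def from_dict(cls, data: dict) -> "FixtureBackend":
        return cls({text: parse_from_dict(d) for text, d in data.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "FixtureBackend":
        return cls.from_dict(json.loads(payload))


def parse(sentence_text: str, backend: ParserBackend) -> ParseResult:
    """Run a backend on one sentence, wrapping failures uniformly."""
    try:
        return backend.parse(sentence_text)
    except (MissingFixtureError, BackendError):
        raise
    except Exception as exc:  # backend bug -> uniform error type
        raise BackendError(f"backend failed on {sentence_text[:60]!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# tree primitives

def _root(node: ConstNode) -> ConstNode:
    while node.parent is not None:
        node = node.parent
    return node


def dominates(ancestor: ConstNode, descendant: ConstNode) -> bool:
    """Proper dominance: ``descendant`` lies strictly inside ``ancestor``'s subtree."""
    if _root(ancestor) is not _root(descendant):
        raise ValueError("nodes belong to different trees")
    node = descendant.parent
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def commands(x: int, y: int, category: str, parse: ParseResult) -> bool:
    """C-command between two token positions, for C in {S, VP, NP, ...}.

    Distinct leaves never dominate one another, so the relation reduces
    to: does the lowest ``category``-labelled ancestor of ``x`` dominate
    ``y``?  False (not an error) when ``x`` has no such ancestor.
    """
    if x == y:
        raise ValueError("command relation is between distinct positions")
    leaves = parse.tree.leaves()
    lx, ly = leaves[x], leaves[y]
    node = lx.parent
    while node is not None and node.label != category:
        node = node.parent
    if node is None:
        return False
    return dominates(node, ly)


@dataclass(frozen=True)
class DepPath:
    exists: bool
    length: int  # undefined (-1) when no path exists
    labels: tuple[str, ...]  # e.g. ("neg/up", "prep/down") in traversal order

    @property
    def direct(self) -> bool:
        return self.exists and self.length == 1


def dep_path(a: int, b: int, parse: ParseResult) -> DepPath:
    """Shortest undirected path between two tokens in the dependency graph.

    Labels carry a direction marker: ``label/up`` when the step runs
    dependent-to-head, ``label/down`` for head-to-dependent.
    """
    n = len(parse.tokens)
    if not (0 <= a < n and 0 <= b < n):
        raise ValueError("token index out of range")
    if a == b:
        return DepPath(True, 0, ())
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
    for e in parse.dep_edges:
        adj[e.head].append((e.dependent, f"{e.label}/down"))
        adj[e.dependent].append((e.head, f"{e.label}/up"))
    prev: dict[int, tuple[int, str]] = {}
    seen = {a}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        for nxt, lab in adj[cur]:
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = (cur, lab)
            if nxt == b:
                labels: list[str] = []
                node = b
                while node != a:
                    node, lab2 = prev[node]
                    labels.append(lab2)
                labels.reverse()
                return DepPath(True, len(labels), tuple(labels))
            queue.append(nxt)
    return DepPath(False, -1, ())


_CLAUSE_LABELS = {"S", "SBAR"}


def cue_scope(cue: CueMatch, parse: ParseResult) -> tuple[int, int]:
    """Token range (inclusive) of the cue's syntactic scope.

    Runs from the cue's first token to the last token of the smallest
    clause-level constituent (S or SBAR) dominating the cue; the whole
    sentence when the cue has no clause ancestor.  Always contiguous and
    containing the cue.
    """
    first = cue.start
    node = parse.leaf_of(first).parent
    while node is not None and node.label not in _CLAUSE_LABELS:
        node = node.parent
    if node is None:
        right = len(parse.tokens) - 1
    else:
        right = node.end - 1
    return (first, max(right, cue.end))


def span_head(start: int, end: int, parse: ParseResult) -> int:
    """Head token of the span [start, end): the token whose dependency
    head lies outside the span (rightmost on ties); the rightmost token
    when every token's head is internal."""
    if not (0 <= start < end <= len(parse.tokens)):
        raise ValueError(f"bad span [{start},{end})")
    head_of: dict[int, int] = {e.dependent: e.head for e in parse.dep_edges}
    best = end - 1
    for i in range(end - 1, start - 1, -1):
        h = head_of.get(i)
        if h is None or not (start <= h < end):
            return i
    return best


def char_span_to_tokens(parse: ParseResult, start: int, end: int) -> tuple[int, int]:
    """Map a sentence-local character span to a token range [first, last].

    Requires tokens to carry character offsets (fixture parses always do).
    """
    hits = []
    for tok in parse.tokens:
        if tok.start is None:
            raise AlignmentError("tokens carry no character offsets")
        tok_end = tok.start + len(tok.text)
        if tok.start < end and tok_end > start:
            hits.append(tok.index)
    if not hits:
        raise AlignmentError(f"char span [{start},{end}) covers no token")
    return (hits[0], hits[-1])


# ---------------------------------------------------------------------------
# (de)serialization — bracketed Penn-style trees, JSON parse records

def tree_to_bracket(node: ConstNode, tokens: Sequence[Token]) -> str:
    if node.is_leaf:
        tok = tokens[node.start]
        return f"({node.label} {tok.text})"
    inner = " ".join(tree_to_bracket(ch, tokens) for ch in node.children)
    return f"({node.label} {inner})"


_BRACKET_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def bracket_to_tree(bracket: str) -> ConstNode:
    """Parse a Penn-style bracketing; leaves are assigned token indices in
    yield order.  Leaf form is ``(LABEL surface)``."""
    toks = _BRACKET_TOKEN.findall(bracket)
    pos = 0
    counter = [0]

    def parse_node() -> ConstNode:
        nonlocal pos
        if toks[pos] != "(":
            raise ValueError(f"expected '(' at {pos}")
        pos += 1
        label = toks[pos]
        pos += 1
        children: list[ConstNode] = []
        leaf_surface: Optional[str] = None
        while toks[pos] != ")":
            if toks[pos] == "(":
                children.append(parse_node())
            else:
                leaf_surface = toks[pos]
                pos += 1
        pos += 1  # consume ')'
        if children:
            node = ConstNode(label, children[0].start, children[-1].end, children)
            return node
        if leaf_surface is None:
            raise ValueError(f"empty constituent {label!r}")
        idx = counter[0]
        counter[0] += 1
        return ConstNode(label, idx, idx + 1)

    root = parse_node()
    if pos != len(toks):
        raise ValueError("trailing material after tree")
    return root


def parse_to_dict(p: ParseResult) -> dict:
    return {
        "tokens": [[t.text, t.lemma, t.pos, t.start] for t in p.tokens],
        "edges": [[e.head, e.dependent, e.label] for e in p.dep_edges],
        "tree": tree_to_bracket(p.tree, p.tokens),
        "connected": p.connected,
    }


def parse_from_dict(data: dict) -> ParseResult:
    tokens = [
        Token(i, text, lemma, pos, start)
        for i, (text, lemma, pos, start) in enumerate(data["tokens"])
    ]
    edges = [DepEdge(h, d, lab) for h, d, lab in data["edges"]]
    tree = bracket_to_tree(data["tree"])
    return ParseResult(tokens, edges, tree, bool(data.get("connected", True)))
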