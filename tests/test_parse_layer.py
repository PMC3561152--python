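"""Tree/graph primitives: dominance, command, dependency paths, cue scope."""

import itertools

import networkx as nx
import numpy as np
import pytest

from negev.cue_lexicon import CueMatch, CueEntry, match_cues, apply_deactivation
from negev.errors import MissingFixtureError
from negev.parse_layer import (
    ConstNode,
    DepEdge,
    DepPath,
    FixtureBackend,
    ParseResult,
    Token,
    bracket_to_tree,
    commands,
    cue_scope,
    dep_path,
    dominates,
    parse,
    parse_from_dict,
    parse_to_dict,
    span_head,
    tree_to_bracket,
)
from negev.synthetic_corpus import VERBS, t_distract_stray_cue, t_neg_trigger_not


def _chain_parse(n, labels=("S",)):
    """A flat parse over n dummy tokens with a chain dependency graph."""
    tokens = [Token(i, f"w{i}", f"w{i}", "NN", i * 3) for i in range(n)]
    leaves = [ConstNode("NN", i, i + 1) for i in range(n)]
    root = ConstNode(labels[0], 0, n, leaves)
    edges = [DepEdge(i, i + 1, "dep") for i in range(n - 1)]
    return ParseResult(tokens, edges, root)


# ---------------------------------------------------------------------------
# dominance

def test_root_dominates_every_leaf_but_not_itself():
    p = _chain_parse(4)
    for leaf in p.tree.leaves():
        assert dominates(p.tree, leaf)
    assert not dominates(p.tree, p.tree)


def test_dominates_rejects_nodes_from_different_trees():
    p1, p2 = _chain_parse(3), _chain_parse(3)
    with pytest.raises(ValueError):
        dominates(p1.tree, p2.tree.leaves()[0])


# ---------------------------------------------------------------------------
# command — exhaustive oracle over enumerated trees

LABELS = ("S", "VP", "NP")


def _shapes(n_leaves):
    """All binary tree shapes with exactly n_leaves leaves, as nested tuples."""
    if n_leaves == 1:
        return [None]
    out = []
    for k in range(1, n_leaves):
        for left in _shapes(k):
            for right in _shapes(n_leaves - k):
                out.append((left, right))
    return out


def _materialize(shape, labeling, counter, li):
    """Build a ConstNode tree from a shape; internal labels drawn from the
    labeling sequence."""
    if shape is None:
        i = counter[0]
        counter[0] += 1
        return ConstNode("TOK", i, i + 1)
    left = _materialize(shape[0], labeling, counter, li)
    right = _materialize(shape[1], labeling, counter, li)
    label = labeling[li[0] % len(labeling)]
    li[0] += 1
    return ConstNode(label, left.start, right.end, [left, right])


def _command_oracle(tree, x, y, category):
    """Direct evaluation of the definition: neither node dominates the
    other, and the smallest-span category-labelled node dominating x also
    dominates y.  Dominance is decided purely by span containment over the
    enumerated node list (valid because binary trees have no unary chains,
    so spans identify nodes)."""
    nodes = list(tree.walk())
    leaves = [n for n in nodes if n.is_leaf]
    lx, ly = leaves[x], leaves[y]

    def dom(a, b):  # proper dominance by strict span containment
        return (a.start <= b.start and b.end <= a.end
                and (a.end - a.start) > (b.end - b.start))

    cands = [n for n in nodes if n.label == category and dom(n, lx)]
    if not cands:
        return False
    lowest = min(cands, key=lambda n: n.end - n.start)
    return dom(lowest, ly)


def test_command_agrees_with_definition_on_all_small_trees():
    """commands() equals a brute-force evaluation of the command
    definition on every binary tree shape with up to 7 leaves, under
    rotating S/VP/NP labelings."""
    rng = np.random.default_rng(5)
    for n_leaves in range(2, 8):
        for shape in _shapes(n_leaves):
            labelings = [tuple(LABELS[(i + off) % 3] for i in range(8)) for off in range(3)]
            labelings.append(tuple(LABELS[int(i)] for i in rng.integers(0, 3, 8)))
            for labeling in labelings:
                tree = _materialize(shape, labeling, [0], [0])
                tokens = [Token(i, f"w{i}", f"w{i}", "NN", i * 3) for i in range(n_leaves)]
                p = ParseResult(tokens, [], tree)
                for x, y in itertools.permutations(range(n_leaves), 2):
                    for cat in LABELS:
                        assert commands(x, y, cat, p) == _command_oracle(tree, x, y, cat)


def test_command_textbook_configuration():
    """In (S (NP x) (VP v (NP y))): x S-commands y, but does not
    NP-command it (the lowest NP over x does not dominate y)."""
    tree = bracket_to_tree("(S (NP (NNP x)) (VP (VBZ v) (NP (NNP y))))")
    tokens = [Token(0, "x", "x", "NNP", 0), Token(1, "v", "v", "VBZ", 2),
              Token(2, "y", "y", "NNP", 4)]
    p = ParseResult(tokens, [], tree)
    assert commands(0, 2, "S", p)
    assert not commands(0, 2, "NP", p)
    # y's lowest NP ancestor covers only y, so it cannot dominate x either
    assert not commands(2, 0, "NP", p)
    assert not commands(2, 0, "VP", p)  # the VP over y does not dominate x


def test_command_requires_distinct_positions():
    p = _chain_parse(3)
    with pytest.raises(ValueError):
        commands(1, 1, "S", p)


# ---------------------------------------------------------------------------
# dependency paths

def test_dep_path_identity_and_direct():
    p = _chain_parse(4)
    assert dep_path(2, 2, p) == DepPath(True, 0, ())
    got = dep_path(0, 1, p)
    assert got.direct and got.length == 1


def test_dep_path_agrees_with_networkx_on_random_graphs():
    """Path lengths equal an all-pairs shortest-path oracle on 200 random
    (possibly disconnected) dependency graphs."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        edges = []
        for i in range(1, n):
            if rng.random() < 0.8:
                edges.append(DepEdge(int(rng.integers(0, i)), i, "dep"))
        tokens = [Token(i, f"w{i}", f"w{i}", "NN", i * 3) for i in range(n)]
        leaves = [ConstNode("NN", i, i + 1) for i in range(n)]
        p = ParseResult(tokens, edges, ConstNode("S", 0, n, leaves))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((e.head, e.dependent) for e in edges)
        a, b = int(rng.integers(0, n)), int(rng.integers(0, n))
        got = dep_path(a, b, p)
        if nx.has_path(g, a, b):
            assert got.exists
            assert got.length == nx.shortest_path_length(g, a, b)
            assert len(got.labels) == got.length
        else:
            assert not got.exists and got.length == -1
        # symmetry
        assert dep_path(b, a, p).length == got.length


# ---------------------------------------------------------------------------
# cue scope

def _cue_at(i):
    return CueMatch(CueEntry(("not",)), (i,))


def test_scope_of_sentence_final_cue_is_cue_itself():
    p = _chain_parse(5)
    assert cue_scope(_cue_at(4), p) == (4, 4)


def test_scope_bounded_by_embedded_clause():
    """A cue inside an adverbial clause scopes to that clause's right
    edge, not to the end of the sentence."""
    verb = VERBS[0]
    spec = t_distract_stray_cue(None, ("Rac1", "STAT1", "CD40"), verb)
    triples = spec.parse.triples()
    matches = match_cues(triples, __import__("negev").load_lexicon("c40"))
    (m,) = [m for m in matches if m.entry.display_name == "absent"]
    lo, hi = cue_scope(m, spec.parse)
    # "absent" is the last token of the embedded S: scope is just the cue
    assert (lo, hi) == (m.start, m.start)
    # the main-clause trigger lies outside the scope
    v_idx = next(t.index for t in spec.parse.tokens if t.lemma == verb[3])
    assert not (lo <= v_idx <= hi)


def test_scope_properties_on_generated_sentences(small_corpus, c40):
    docs, backend, _ = small_corpus
    for doc in docs[:40]:
        for sent in doc.sentences:
            p = parse(sent.text, backend)
            for m in apply_deactivation(match_cues(p.triples(), c40), p.triples()):
                lo, hi = cue_scope(m, p)
                assert 0 <= lo <= hi < len(p.tokens)
                assert lo == m.start and hi >= m.end


# ---------------------------------------------------------------------------
# backends, serialization, heads

def test_fixture_backend_exact_lookup_and_missing(small_corpus):
    docs, backend, _ = small_corpus
    sent = docs[0].sentences[0]
    p = parse(sent.text, backend)
    assert p.tokens and p.tree.end == len(p.tokens)
    with pytest.raises(MissingFixtureError):
        parse("This sentence has no fixture.", backend)


def test_parse_serialization_roundtrip_is_bitwise_stable(small_corpus):
    _, backend, _ = small_corpus
    once = backend.to_json()
    again = FixtureBackend.from_json(once).to_json()
    assert once == again


def test_tree_yield_matches_tokens_everywhere(small_corpus):
    docs, backend, _ = small_corpus
    for doc in docs[:40]:
        for sent in doc.sentences:
            p = parse(sent.text, backend)
            assert [l.start for l in p.tree.leaves()] == [t.index for t in p.tokens]


def test_one_token_sentence():
    tokens = [Token(0, "Hello", "hello", "UH", 0)]
    p = ParseResult(tokens, [], ConstNode("UH", 0, 1))
    assert p.tree.is_leaf and p.dep_edges == []
    assert tree_to_bracket(p.tree, tokens) == "(UH Hello)"


def test_bracket_roundtrip():
    spec = t_neg_trigger_not(None, ("Rac1", "STAT1"), VERBS[0])
    d = parse_to_dict(spec.parse)
    again = parse_from_dict(d)
    assert parse_to_dict(again) == d


def test_span_head_picks_token_with_external_head():
    spec = t_neg_trigger_not(None, ("Rac1", "STAT1"), VERBS[0])
    p = spec.parse
    # "did not <verb>" span: the verb's head (nsubj from outside) -> verb is head
    v_idx = next(t.index for t in p.tokens if t.pos == "VB")
    assert span_head(1, v_idx + 1, p) == v_idx
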