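"""Synthetic standoff corpus generator with planted negated bio-events.

Each sentence is instantiated from a closed set of templates patterned on
how negation actually manifests around bio-events:

* **inherent** — the trigger itself is a negative word (*unaffected*,
  *independent*);
* **trigger** — an explicit cue syntactically modifies the trigger
  (*did not activate*, *failed to activate*);
* **participant** — the cue modifies a participant phrase
  (*not A but B activated C*);
* **attribute** — the cue modifies a location phrase
  (*... , though not in monocytic cells*);
* **contrast** — the negation is signalled by a contrastive construction
  with no explicit cue (*In contrast to A , B activated C*), the hard
  case that bounds recall for any cue-driven feature scheme.

Non-negated sentences include *distractors*: the deactivated ``not only``
construction, and stray cues in adverbial clauses that scope over no
negated event — so cue presence alone is a poor predictor, as it is in
real corpora.  One template variant plants a negated first clause next to
a positive co-event whose trigger falls inside the cue's scope.

Every template carries its own tokenisation, lemmas, POS tags, dependency
skeleton and constituency bracketing, so the emitted
:class:`~negev.parse_layer.FixtureBackend` is exact and the whole corpus
is byte-reproducible from the seed.  Default rates mirror what is
observed in open bio-event corpora: a 6.3% sentence negation rate, a
negated-type mix of 12/63/11/6/8 percent
(inherent/trigger/participant/attribute/contrast), and complex events
2.5 times more likely to be negated than simple ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cue_lexicon import CueLexicon, load_lexicon
from .errors import NegevError
from .parse_layer import ConstNode, DepEdge, FixtureBackend, ParseResult, Token
from .standoff_io import (
    NEGATED,
    POSITIVE,
    BioEvent,
    Document,
    Entity,
    Participant,
    TextSpan,
)

NEGATION_TYPES = ("inherent", "trigger", "participant", "attribute", "contrast")

DEFAULT_TYPE_MIX = {
    "inherent": 0.12,
    "trigger": 0.63,
    "participant": 0.11,
    "attribute": 0.06,
    "contrast": 0.08,
}

PROTEINS = (
    "IL-2", "NF-kappaB", "Rac1", "STAT1", "IFN-gamma", "TNF-alpha", "CD40",
    "IkBalpha", "c-Fos", "c-Jun", "p38", "MKK3", "Cdc42", "TRAF2", "c-Myc",
    "GATA1", "SOCS3", "FOXP3", "IL-12", "IRF-1",
)

CELL_ADJS = ("monocytic", "epithelial", "lymphoid", "endothelial", "myeloid")

# (3sg, past, base, lemma, event_type)
VERBS = (
    ("activates", "activated", "activate", "activate", "positive_regulation"),
    ("induces", "induced", "induce", "induce", "positive_regulation"),
    ("stimulates", "stimulated", "stimulate", "stimulate", "positive_regulation"),
    ("inhibits", "inhibited", "inhibit", "inhibit", "negative_regulation"),
    ("suppresses", "suppressed", "suppress", "suppress", "negative_regulation"),
    ("regulates", "regulated", "regulate", "regulate", "regulation"),
    ("modulates", "modulated", "modulate", "modulate", "regulation"),
    ("binds", "bound", "bind", "bind", "binding"),
    ("phosphorylates", "phosphorylated", "phosphorylate", "phosphorylate", "phosphorylation"),
)

# (surface_noun, lemma, event_type) for embedded "the <noun> of X"
EVENT_NOUNS = (
    ("expression", "expression", "gene_expression"),
    ("transcription", "transcription", "transcription"),
    ("phosphorylation", "phosphorylation", "phosphorylation"),
    ("degradation", "degradation", "protein_catabolism"),
    ("localization", "localization", "localization"),
)

# (past-participle, lemma, event_type) for passives with a location
PASSIVES = (
    ("expressed", "express", "gene_expression"),
    ("transcribed", "transcribe", "transcription"),
    ("phosphorylated", "phosphorylate", "phosphorylation"),
)


@dataclass
class GeneratorConfig:
    n_sentences: int = 1000
    negation_rate: float = 0.063
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    cue_inventory: str = "c40"
    complex_event_rate: float = 0.25
    negation_enrichment_complex: float = 2.5
    cue_choice: str = "mixed"  # "mixed" | "not" | "fail" for trigger negations
    deactivated_distractor_rate: float = 0.10
    stray_cue_distractor_rate: float = 0.10
    sentences_per_doc: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sentences < 0:
            raise NegevError("n_sentences must be non-negative")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise NegevError("negation_rate must lie in [0, 1]")
        if not 0.0 <= self.complex_event_rate <= 1.0:
            raise NegevError("complex_event_rate must lie in [0, 1]")
        if set(self.type_mix) - set(NEGATION_TYPES):
            raise NegevError(f"unknown negation types in mix: {self.type_mix}")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise NegevError("type_mix must sum to 1")
        if self.cue_choice not in ("mixed", "not", "fail"):
            raise NegevError("cue_choice must be mixed|not|fail")
        d = self.deactivated_distractor_rate + self.stray_cue_distractor_rate
        if d > 1.0:
            raise NegevError("distractor rates sum above 1")


@dataclass(frozen=True)
class GoldRecord:
    doc_id: str
    event_id: str
    polarity: str
    negation_type: Optional[str]
    template_id: str
    is_complex: bool
    sentence_index: int

    @property
    def key(self) -> str:
        return f"{self.doc_id}/{self.event_id}"


# ---------------------------------------------------------------------------
# sentence assembly machinery

@dataclass
class EventSpec:
    event_type: str
    trigger: tuple[int, int]  # token range, inclusive
    participants: list[tuple[str, tuple[str, int]]]  # (role, ("entity"|"event", idx))
    location: Optional[int] = None  # entity index
    polarity: str = POSITIVE
    negation_type: Optional[str] = None


@dataclass
class SentenceSpec:
    template_id: str
    parse: ParseResult
    text: str
    entities: list[tuple[str, int, int]]  # (semantic_type, first_tok, last_tok)
    events: list[EventSpec]


class _SB:
    """Incremental sentence builder: tokens, dependency edges, tree nodes."""

    def __init__(self) -> None:
        self.toks: list[tuple[str, str, str]] = []
        self.edges: list[DepEdge] = []

    def tok(self, text: str, lemma: str, pos: str) -> int:
        self.toks.append((text, lemma, pos))
        return len(self.toks) - 1

    def edge(self, head: int, dep: int, label: str) -> None:
        self.edges.append(DepEdge(head, dep, label))

    def leaf(self, i: int) -> ConstNode:
        return ConstNode(self.toks[i][2], i, i + 1)

    def node(self, label: str, children: list) -> ConstNode:
        kids = [c if isinstance(c, ConstNode) else self.leaf(c) for c in children]
        return ConstNode(label, kids[0].start, kids[-1].end, kids)

    def finish(self, root: ConstNode) -> tuple[str, ParseResult]:
        tokens: list[Token] = []
        pos = 0
        for i, (text, lemma, tag) in enumerate(self.toks):
            tokens.append(Token(i, text, lemma, tag, pos))
            pos += len(text) + 1
        text = " ".join(t[0] for t in self.toks)
        return text, ParseResult(tokens, self.edges, root)


def _finish_spec(template_id: str, sb: _SB, root: ConstNode,
                 entities, events) -> SentenceSpec:
    text, parse = sb.finish(root)
    return SentenceSpec(template_id, parse, text, entities, events)


def _np(sb: _SB, name: str):
    i = sb.tok(name, name, "NNP")
    return sb.node("NP", [i]), i


def _np_the_noun_of(sb: _SB, noun: tuple[str, str, str], name: str):
    """'the <event-noun> of <name>' — returns (node, noun_idx, name_idx)."""
    d = sb.tok("the", "the", "DT")
    n = sb.tok(noun[0], noun[1], "NN")
    of = sb.tok("of", "of", "IN")
    e = sb.tok(name, name, "NNP")
    sb.edge(n, d, "det")
    sb.edge(n, of, "prep")
    sb.edge(of, e, "pobj")
    node = sb.node("NP", [d, n, sb.node("PP", [of, sb.node("NP", [e])])])
    return node, n, e


def _pp_in_cells(sb: _SB, adj: str, extra_leading: Optional[list[int]] = None):
    """'in <adj> cells' — returns (node, in_idx, (adj_idx, cells_idx))."""
    p = sb.tok("in", "in", "IN")
    a = sb.tok(adj, adj, "JJ")
    c = sb.tok("cells", "cell", "NNS")
    sb.edge(p, c, "pobj")
    sb.edge(c, a, "amod")
    leading = extra_leading or []
    node = sb.node("PP", leading + [p, sb.node("NP", [a, c])])
    return node, p, (a, c)


# ---------------------------------------------------------------------------
# templates — each returns a SentenceSpec

def t_pos_simple_verb(rng, names, verb) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    v = sb.tok(verb[0], verb[3], "VBZ")
    np_b, ib = _np(sb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubj")
    sb.edge(v, ib, "dobj")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [v, np_b]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))])
    return _finish_spec("pos_simple_verb", sb, root, ents, [ev])


def t_pos_simple_loc(rng, names, passive, cell_adj) -> SentenceSpec:
    (a,) = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    was = sb.tok("was", "be", "VBD")
    v = sb.tok(passive[0], passive[1], "VBN")
    pp, p_in, (ic1, ic2) = _pp_in_cells(sb, cell_adj)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubjpass")
    sb.edge(v, was, "auxpass")
    sb.edge(v, p_in, "prep")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [was, sb.node("VP", [v, pp])]), dot])
    ents = [("protein", ia, ia), ("cell_type", ic1, ic2)]
    ev = EventSpec(passive[2], (v, v), [("theme", ("entity", 0))], location=1)
    return _finish_spec("pos_simple_loc", sb, root, ents, [ev])


def t_pos_simple_past(rng, names, verb) -> SentenceSpec:
    """'A <v>ed B .' — past-tense positive control."""
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    v = sb.tok(verb[1], verb[3], "VBD")
    np_b, ib = _np(sb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubj")
    sb.edge(v, ib, "dobj")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [v, np_b]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))])
    return _finish_spec("pos_simple_past", sb, root, ents, [ev])


def t_pos_simple_inf(rng, names, verb) -> SentenceSpec:
    """'A continued to <v> B .' — a positive control with an infinitival
    trigger, mirroring the surface shape of 'failed to <v>'."""
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    cont = sb.tok("continued", "continue", "VBD")
    to = sb.tok("to", "to", "TO")
    v = sb.tok(verb[2], verb[3], "VB")
    np_b, ib = _np(sb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(cont, ia, "nsubj")
    sb.edge(cont, v, "xcomp")
    sb.edge(v, to, "aux")
    sb.edge(v, ib, "dobj")
    sb.edge(cont, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [cont, sb.node("VP", [to, v, np_b])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))])
    return _finish_spec("pos_simple_inf", sb, root, ents, [ev])


def t_pos_complex_inf(rng, names, verb, noun) -> SentenceSpec:
    """'A continued to <v> the <noun> of B .'"""
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    cont = sb.tok("continued", "continue", "VBD")
    to = sb.tok("to", "to", "TO")
    v = sb.tok(verb[2], verb[3], "VB")
    np_obj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(cont, ia, "nsubj")
    sb.edge(cont, v, "xcomp")
    sb.edge(v, to, "aux")
    sb.edge(v, i_noun, "dobj")
    sb.edge(cont, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [cont, sb.node("VP", [to, v, np_obj])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))])
    return _finish_spec("pos_complex_inf", sb, root, ents, [inner, outer])


def t_pos_complex(rng, names, verb, noun, past: bool = False) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    v = sb.tok(verb[1] if past else verb[0], verb[3], "VBD" if past else "VBZ")
    np_obj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubj")
    sb.edge(v, i_noun, "dobj")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [v, np_obj]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))])
    return _finish_spec("pos_complex", sb, root, ents, [inner, outer])


def t_distract_not_only(rng, names, verb) -> SentenceSpec:
    """'Not only A but also B <v>ed C .' — both events positive; the cue
    *not* is deactivated by *only*."""
    a, b, c = names
    sb = _SB()
    nt = sb.tok("Not", "not", "RB")
    only = sb.tok("only", "only", "RB")
    ia = sb.tok(a, a, "NNP")
    but = sb.tok("but", "but", "CC")
    also = sb.tok("also", "also", "RB")
    ib = sb.tok(b, b, "NNP")
    v = sb.tok(verb[1], verb[3], "VBD")
    np_c, ic = _np(sb, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(ia, nt, "neg")
    sb.edge(nt, only, "advmod")
    sb.edge(v, ia, "nsubj")
    sb.edge(ia, but, "cc")
    sb.edge(ia, ib, "conj")
    sb.edge(ib, also, "advmod")
    sb.edge(v, ic, "dobj")
    sb.edge(v, dot, "punct")
    subj = sb.node("NP", [sb.node("NP", [nt, only, ia]), but,
                          sb.node("NP", [also, ib])])
    root = sb.node("S", [subj, sb.node("VP", [v, np_c]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    e1 = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 2)), ("cause", ("entity", 0))])
    e2 = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 2)), ("cause", ("entity", 1))])
    return _finish_spec("distract_not_only", sb, root, ents, [e1, e2])


def t_distract_stray_cue(rng, names, verb) -> SentenceSpec:
    """'Although A was absent , B <v>ed C .' — the cue sits in an adverbial
    clause; the annotated event is positive."""
    a, b, c = names
    sb = _SB()
    alt = sb.tok("Although", "although", "IN")
    ia = sb.tok(a, a, "NNP")
    was = sb.tok("was", "be", "VBD")
    absent = sb.tok("absent", "absent", "JJ")
    comma = sb.tok(",", ",", ",")
    np_b, ib = _np(sb, b)
    v = sb.tok(verb[1], verb[3], "VBD")
    np_c, ic = _np(sb, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(absent, alt, "mark")
    sb.edge(absent, ia, "nsubj")
    sb.edge(absent, was, "cop")
    sb.edge(v, absent, "advcl")
    sb.edge(v, comma, "punct")
    sb.edge(v, ib, "nsubj")
    sb.edge(v, ic, "dobj")
    sb.edge(v, dot, "punct")
    sub = sb.node("SBAR", [alt, sb.node("S", [sb.node("NP", [ia]),
                                              sb.node("VP", [was, sb.node("ADJP", [absent])])])])
    root = sb.node("S", [sub, comma, np_b, sb.node("VP", [v, np_c]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 2)), ("cause", ("entity", 1))])
    return _finish_spec("distract_stray_cue", sb, root, ents, [ev])


def _clause_did_not(sb: _SB, a: str, verb, b: str):
    """'A did not <v> B' — returns pieces for reuse."""
    np_a, ia = _np(sb, a)
    did = sb.tok("did", "do", "VBD")
    nt = sb.tok("not", "not", "RB")
    v = sb.tok(verb[2], verb[3], "VB")
    np_b, ib = _np(sb, b)
    sb.edge(v, ia, "nsubj")
    sb.edge(v, did, "aux")
    sb.edge(v, nt, "neg")
    sb.edge(v, ib, "dobj")
    vp = sb.node("VP", [did, nt, sb.node("VP", [v, np_b])])
    return np_a, ia, v, ib, vp


def t_neg_trigger_not(rng, names, verb) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia, v, ib, vp = _clause_did_not(sb, a, verb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, vp, dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))],
                   polarity=NEGATED, negation_type="trigger")
    return _finish_spec("neg_trigger_not", sb, root, ents, [ev])


def t_neg_trigger_fail(rng, names, verb) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    failed = sb.tok("failed", "fail", "VBD")
    to = sb.tok("to", "to", "TO")
    v = sb.tok(verb[2], verb[3], "VB")
    np_b, ib = _np(sb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(failed, ia, "nsubj")
    sb.edge(failed, v, "xcomp")
    sb.edge(v, to, "aux")
    sb.edge(v, ib, "dobj")
    sb.edge(failed, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [failed, sb.node("VP", [to, v, np_b])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))],
                   polarity=NEGATED, negation_type="trigger")
    return _finish_spec("neg_trigger_fail", sb, root, ents, [ev])


def t_neg_trigger_coevent(rng, names, verbs) -> SentenceSpec:
    """'A did not <v1> B , whereas C <v2>ed D .' — a negated first clause
    plus a positive co-event whose trigger falls inside the cue's scope."""
    a, b, c, d = names
    v1, v2 = verbs
    sb = _SB()
    np_a, ia, tv1, ib, vp1 = _clause_did_not(sb, a, v1, b)
    comma = sb.tok(",", ",", ",")
    wh = sb.tok("whereas", "whereas", "IN")
    np_c, ic = _np(sb, c)
    tv2 = sb.tok(v2[1], v2[3], "VBD")
    np_d, idd = _np(sb, d)
    dot = sb.tok(".", ".", ".")
    sb.edge(tv1, comma, "punct")
    sb.edge(tv2, wh, "mark")
    sb.edge(tv2, ic, "nsubj")
    sb.edge(tv2, idd, "dobj")
    sb.edge(tv1, tv2, "advcl")
    sb.edge(tv1, dot, "punct")
    sub = sb.node("SBAR", [wh, sb.node("S", [np_c, sb.node("VP", [tv2, np_d])])])
    root = sb.node("S", [np_a, vp1, comma, sub, dot])
    ents = [("protein", ia, ia), ("protein", ib, ib),
            ("protein", ic, ic), ("protein", idd, idd)]
    e1 = EventSpec(v1[4], (tv1, tv1),
                   [("theme", ("entity", 1)), ("cause", ("entity", 0))],
                   polarity=NEGATED, negation_type="trigger")
    e2 = EventSpec(v2[4], (tv2, tv2),
                   [("theme", ("entity", 3)), ("cause", ("entity", 2))])
    return _finish_spec("neg_trigger_coevent", sb, root, ents, [e1, e2])


def t_neg_inherent(rng, names, cue_word) -> SentenceSpec:
    """'A was <unaffected by|independent of> B .' — the trigger IS the cue."""
    a, b = names
    prep_word = "by" if cue_word == "unaffected" else "of"
    sb = _SB()
    np_a, ia = _np(sb, a)
    was = sb.tok("was", "be", "VBD")
    cue = sb.tok(cue_word, cue_word, "JJ")
    prep = sb.tok(prep_word, prep_word, "IN")
    np_b, ib = _np(sb, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(cue, ia, "nsubj")
    sb.edge(cue, was, "cop")
    sb.edge(cue, prep, "prep")
    sb.edge(prep, ib, "pobj")
    sb.edge(cue, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [was, sb.node("ADJP", [cue, sb.node("PP", [prep, np_b])])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    ev = EventSpec("regulation", (cue, cue),
                   [("theme", ("entity", 0)), ("cause", ("entity", 1))],
                   polarity=NEGATED, negation_type="inherent")
    return _finish_spec(f"neg_inherent_{cue_word}", sb, root, ents, [ev])


def t_neg_participant(rng, names, verb) -> SentenceSpec:
    """'not A but B <v>ed C .' — the cue modifies the negated cause."""
    a, b, c = names
    sb = _SB()
    nt = sb.tok("not", "not", "RB")
    ia = sb.tok(a, a, "NNP")
    but = sb.tok("but", "but", "CC")
    ib = sb.tok(b, b, "NNP")
    v = sb.tok(verb[1], verb[3], "VBD")
    np_c, ic = _np(sb, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(ia, nt, "neg")
    sb.edge(v, ib, "nsubj")
    sb.edge(ib, ia, "conj")
    sb.edge(ib, but, "cc")
    sb.edge(v, ic, "dobj")
    sb.edge(v, dot, "punct")
    subj = sb.node("NP", [sb.node("NP", [nt, ia]), but, sb.node("NP", [ib])])
    root = sb.node("S", [subj, sb.node("VP", [v, np_c]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    # only the negated event is annotated: its positive twin differs solely
    # in which conjunct fills the cause slot, which the feature inventory
    # (cue<->trigger / cue<->location relations) cannot see
    ev = EventSpec(verb[4], (v, v),
                   [("theme", ("entity", 2)), ("cause", ("entity", 0))],
                   polarity=NEGATED, negation_type="participant")
    return _finish_spec("neg_participant", sb, root, ents, [ev])


def t_neg_attribute(rng, names, passive, cell_adj) -> SentenceSpec:
    """'A was <v>ed , though not in <adj> cells .' — cue modifies location."""
    (a,) = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    was = sb.tok("was", "be", "VBD")
    v = sb.tok(passive[0], passive[1], "VBN")
    comma = sb.tok(",", ",", ",")
    though = sb.tok("though", "though", "IN")
    nt = sb.tok("not", "not", "RB")
    pp, p_in, (ic1, ic2) = _pp_in_cells(sb, cell_adj, extra_leading=[nt])
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubjpass")
    sb.edge(v, was, "auxpass")
    sb.edge(v, comma, "punct")
    sb.edge(v, though, "mark")
    sb.edge(p_in, nt, "neg")
    sb.edge(v, p_in, "prep")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [was, v, comma, though, pp]), dot])
    ents = [("protein", ia, ia), ("cell_type", ic1, ic2)]
    ev = EventSpec(passive[2], (v, v), [("theme", ("entity", 0))], location=1,
                   polarity=NEGATED, negation_type="attribute")
    return _finish_spec("neg_attribute", sb, root, ents, [ev])


def t_neg_contrast(rng, names, verb) -> SentenceSpec:
    """'In contrast to A , B <v>ed C .' — no explicit cue; both the negated
    event (cause A) and its positive twin (cause B) are annotated."""
    a, b, c = names
    sb = _SB()
    p_in = sb.tok("In", "in", "IN")
    contrast = sb.tok("contrast", "contrast", "NN")
    to = sb.tok("to", "to", "IN")
    ia = sb.tok(a, a, "NNP")
    comma = sb.tok(",", ",", ",")
    np_b, ib = _np(sb, b)
    v = sb.tok(verb[1], verb[3], "VBD")
    np_c, ic = _np(sb, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(p_in, contrast, "pobj")
    sb.edge(contrast, to, "prep")
    sb.edge(to, ia, "pobj")
    sb.edge(v, p_in, "prep")
    sb.edge(v, comma, "punct")
    sb.edge(v, ib, "nsubj")
    sb.edge(v, ic, "dobj")
    sb.edge(v, dot, "punct")
    pp = sb.node("PP", [p_in, sb.node("NP", [contrast,
                 sb.node("PP", [to, sb.node("NP", [ia])])])])
    root = sb.node("S", [pp, comma, np_b, sb.node("VP", [v, np_c]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    e_pos = EventSpec(verb[4], (v, v),
                      [("theme", ("entity", 2)), ("cause", ("entity", 1))])
    e_neg = EventSpec(verb[4], (v, v),
                      [("theme", ("entity", 2)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="contrast")
    return _finish_spec("neg_contrast", sb, root, ents, [e_pos, e_neg])


# --- complex (nested) variants ---------------------------------------------

def t_negc_trigger_not(rng, names, verb, noun) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    did = sb.tok("did", "do", "VBD")
    nt = sb.tok("not", "not", "RB")
    v = sb.tok(verb[2], verb[3], "VB")
    np_obj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubj")
    sb.edge(v, did, "aux")
    sb.edge(v, nt, "neg")
    sb.edge(v, i_noun, "dobj")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [did, nt, sb.node("VP", [v, np_obj])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="trigger")
    return _finish_spec("negc_trigger_not", sb, root, ents, [inner, outer])


def t_negc_trigger_fail(rng, names, verb, noun) -> SentenceSpec:
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    failed = sb.tok("failed", "fail", "VBD")
    to = sb.tok("to", "to", "TO")
    v = sb.tok(verb[2], verb[3], "VB")
    np_obj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    dot = sb.tok(".", ".", ".")
    sb.edge(failed, ia, "nsubj")
    sb.edge(failed, v, "xcomp")
    sb.edge(v, to, "aux")
    sb.edge(v, i_noun, "dobj")
    sb.edge(failed, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [failed, sb.node("VP", [to, v, np_obj])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="trigger")
    return _finish_spec("negc_trigger_fail", sb, root, ents, [inner, outer])


def t_negc_inherent(rng, names, noun) -> SentenceSpec:
    """'The <noun> of B was independent of A .'"""
    a, b = names
    sb = _SB()
    np_subj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    was = sb.tok("was", "be", "VBD")
    cue = sb.tok("independent", "independent", "JJ")
    of2 = sb.tok("of", "of", "IN")
    np_a, ia = _np(sb, a)
    dot = sb.tok(".", ".", ".")
    sb.edge(cue, i_noun, "nsubj")
    sb.edge(cue, was, "cop")
    sb.edge(cue, of2, "prep")
    sb.edge(of2, ia, "pobj")
    sb.edge(cue, dot, "punct")
    root = sb.node("S", [np_subj, sb.node("VP", [was, sb.node("ADJP", [cue, sb.node("PP", [of2, np_a])])]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec("regulation", (cue, cue),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="inherent")
    return _finish_spec("negc_inherent", sb, root, ents, [inner, outer])


def t_negc_participant(rng, names, verb, noun) -> SentenceSpec:
    """'not A but B <v>ed the <noun> of C .'"""
    a, b, c = names
    sb = _SB()
    nt = sb.tok("not", "not", "RB")
    ia = sb.tok(a, a, "NNP")
    but = sb.tok("but", "but", "CC")
    ib = sb.tok(b, b, "NNP")
    v = sb.tok(verb[1], verb[3], "VBD")
    np_obj, i_noun, ic = _np_the_noun_of(sb, noun, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(ia, nt, "neg")
    sb.edge(v, ib, "nsubj")
    sb.edge(ib, ia, "conj")
    sb.edge(ib, but, "cc")
    sb.edge(v, i_noun, "dobj")
    sb.edge(v, dot, "punct")
    subj = sb.node("NP", [sb.node("NP", [nt, ia]), but, sb.node("NP", [ib])])
    root = sb.node("S", [subj, sb.node("VP", [v, np_obj]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 2))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="participant")
    return _finish_spec("negc_participant", sb, root, ents, [inner, outer])


def t_negc_attribute(rng, names, verb, noun, cell_adj) -> SentenceSpec:
    """'A <v>ed the <noun> of B , though not in <adj> cells .'"""
    a, b = names
    sb = _SB()
    np_a, ia = _np(sb, a)
    v = sb.tok(verb[1], verb[3], "VBD")
    np_obj, i_noun, ib = _np_the_noun_of(sb, noun, b)
    comma = sb.tok(",", ",", ",")
    though = sb.tok("though", "though", "IN")
    nt = sb.tok("not", "not", "RB")
    pp, p_in, (ic1, ic2) = _pp_in_cells(sb, cell_adj, extra_leading=[nt])
    dot = sb.tok(".", ".", ".")
    sb.edge(v, ia, "nsubj")
    sb.edge(v, i_noun, "dobj")
    sb.edge(v, comma, "punct")
    sb.edge(v, though, "mark")
    sb.edge(p_in, nt, "neg")
    sb.edge(v, p_in, "prep")
    sb.edge(v, dot, "punct")
    root = sb.node("S", [np_a, sb.node("VP", [v, np_obj, comma, though, pp]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("cell_type", ic1, ic2)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 1))])
    outer = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      location=2, polarity=NEGATED, negation_type="attribute")
    return _finish_spec("negc_attribute", sb, root, ents, [inner, outer])


def t_negc_contrast(rng, names, verb, noun) -> SentenceSpec:
    """'In contrast to A , B <v>ed the <noun> of C .'"""
    a, b, c = names
    sb = _SB()
    p_in = sb.tok("In", "in", "IN")
    contrast = sb.tok("contrast", "contrast", "NN")
    to = sb.tok("to", "to", "IN")
    ia = sb.tok(a, a, "NNP")
    comma = sb.tok(",", ",", ",")
    np_b, ib = _np(sb, b)
    v = sb.tok(verb[1], verb[3], "VBD")
    np_obj, i_noun, ic = _np_the_noun_of(sb, noun, c)
    dot = sb.tok(".", ".", ".")
    sb.edge(p_in, contrast, "pobj")
    sb.edge(contrast, to, "prep")
    sb.edge(to, ia, "pobj")
    sb.edge(v, p_in, "prep")
    sb.edge(v, comma, "punct")
    sb.edge(v, ib, "nsubj")
    sb.edge(v, i_noun, "dobj")
    sb.edge(v, dot, "punct")
    pp = sb.node("PP", [p_in, sb.node("NP", [contrast,
                 sb.node("PP", [to, sb.node("NP", [ia])])])])
    root = sb.node("S", [pp, comma, np_b, sb.node("VP", [v, np_obj]), dot])
    ents = [("protein", ia, ia), ("protein", ib, ib), ("protein", ic, ic)]
    inner = EventSpec(noun[2], (i_noun, i_noun), [("theme", ("entity", 2))])
    e_pos = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 1))])
    e_neg = EventSpec(verb[4], (v, v),
                      [("theme", ("event", 0)), ("cause", ("entity", 0))],
                      polarity=NEGATED, negation_type="contrast")
    return _finish_spec("negc_contrast", sb, root, ents, [inner, e_pos, e_neg])


# ---------------------------------------------------------------------------
# the generator

def _pick(rng: np.random.Generator, seq, n=1):
    idx = rng.choice(len(seq), size=n, replace=False)
    items = [seq[int(i)] for i in idx]
    return items[0] if n == 1 else items


def _draw_sentence(rng: np.random.Generator, cfg: GeneratorConfig,
                   lexicon_lemmas: frozenset) -> SentenceSpec:
    is_cx = rng.random() < cfg.complex_event_rate
    # per-sentence negation probability; complex sentences are enriched so
    # that the marginal rate stays at cfg.negation_rate
    e = cfg.negation_enrichment_complex
    c = cfg.complex_event_rate
    p_simple = cfg.negation_rate / ((1 - c) + c * e) if cfg.negation_rate else 0.0
    p = min(1.0, p_simple * e) if is_cx else min(1.0, p_simple)
    negated = rng.random() < p

    verb = _pick(rng, VERBS)
    noun = _pick(rng, EVENT_NOUNS)
    passive = _pick(rng, PASSIVES)
    cell = _pick(rng, CELL_ADJS)

    if not negated:
        u = rng.random()
        if u < cfg.deactivated_distractor_rate:
            return t_distract_not_only(rng, _pick(rng, PROTEINS, 3), verb)
        if u < cfg.deactivated_distractor_rate + cfg.stray_cue_distractor_rate:
            return t_distract_stray_cue(rng, _pick(rng, PROTEINS, 3), verb)
        if is_cx:
            u3 = rng.random()
            if u3 < 0.25:
                return t_pos_complex_inf(rng, _pick(rng, PROTEINS, 2), verb, noun)
            return t_pos_complex(rng, _pick(rng, PROTEINS, 2), verb, noun,
                                 past=u3 < 0.55)
        u2 = rng.random()
        if u2 < 0.25:
            return t_pos_simple_loc(rng, [_pick(rng, PROTEINS)], passive, cell)
        if u2 < 0.45:
            return t_pos_simple_inf(rng, _pick(rng, PROTEINS, 2), verb)
        if u2 < 0.70:
            return t_pos_simple_past(rng, _pick(rng, PROTEINS, 2), verb)
        return t_pos_simple_verb(rng, _pick(rng, PROTEINS, 2), verb)

    ntype = NEGATION_TYPES[
        int(rng.choice(len(NEGATION_TYPES),
                       p=[cfg.type_mix.get(t, 0.0) for t in NEGATION_TYPES]))
    ]
    if ntype == "trigger":
        if cfg.cue_choice == "not":
            cue = "not"
        elif cfg.cue_choice == "fail":
            cue = "fail"
        else:
            cue = ["not", "fail", "coevent"][int(rng.choice(3, p=[0.6, 0.25, 0.15]))]
        if is_cx:
            if cue == "fail":
                return t_negc_trigger_fail(rng, _pick(rng, PROTEINS, 2), verb, noun)
            return t_negc_trigger_not(rng, _pick(rng, PROTEINS, 2), verb, noun)
        if cue == "fail":
            return t_neg_trigger_fail(rng, _pick(rng, PROTEINS, 2), verb)
        if cue == "coevent":
            return t_neg_trigger_coevent(rng, _pick(rng, PROTEINS, 4),
                                         _pick(rng, VERBS, 2))
        return t_neg_trigger_not(rng, _pick(rng, PROTEINS, 2), verb)
    if ntype == "inherent":
        if is_cx:
            return t_negc_inherent(rng, _pick(rng, PROTEINS, 2), noun)
        candidates = [w for w in ("unaffected", "independent") if w in lexicon_lemmas]
        cue_word = _pick(rng, candidates or ["unaffected"])
        return t_neg_inherent(rng, _pick(rng, PROTEINS, 2), cue_word)
    if ntype == "participant":
        if is_cx:
            return t_negc_participant(rng, _pick(rng, PROTEINS, 3), verb, noun)
        return t_neg_participant(rng, _pick(rng, PROTEINS, 3), verb)
    if ntype == "attribute":
        if is_cx:
            return t_negc_attribute(rng, _pick(rng, PROTEINS, 2), verb, noun, cell)
        return t_neg_attribute(rng, [_pick(rng, PROTEINS)], passive, cell)
    # contrast
    if is_cx:
        return t_negc_contrast(rng, _pick(rng, PROTEINS, 3), verb, noun)
    return t_neg_contrast(rng, _pick(rng, PROTEINS, 3), verb)


def _assemble_document(doc_id: str, specs: list[SentenceSpec]
                       ) -> tuple[Document, list[GoldRecord]]:
    lines = [s.text for s in specs]
    text = "\n".join(lines)
    sentences: list[TextSpan] = []
    pos = 0
    for line in lines:
        sentences.append(TextSpan(pos, pos + len(line), line))
        pos += len(line) + 1

    entities: list[Entity] = []
    events: list[BioEvent] = []
    gold: list[GoldRecord] = []
    t_count = 0
    e_count = 0
    for si, spec in enumerate(specs):
        off = sentences[si].start
        toks = spec.parse.tokens

        def tok_span(first: int, last: int) -> TextSpan:
            start = toks[first].start + off
            end = toks[last].start + len(toks[last].text) + off
            return TextSpan(start, end, text[start:end])

        local_ents: list[Entity] = []
        for stype, first, last in spec.entities:
            t_count += 1
            ent = Entity(f"T{t_count}", stype, tok_span(first, last))
            local_ents.append(ent)
            entities.append(ent)
        local_events: list[BioEvent] = []
        for es in spec.events:
            e_count += 1
            ev = BioEvent(f"E{e_count}", es.event_type,
                          tok_span(es.trigger[0], es.trigger[1]),
                          polarity=es.polarity)
            for role, (kind, idx) in es.participants:
                filler = local_events[idx] if kind == "event" else local_ents[idx]
                ev.participants.append(Participant(role, filler))
            if es.location is not None:
                ev.attributes["location"] = local_ents[es.location]
            local_events.append(ev)
            events.append(ev)
            gold.append(GoldRecord(
                doc_id, ev.id, es.polarity, es.negation_type, spec.template_id,
                any(kind == "event" for _, (kind, _) in es.participants), si,
            ))
    doc = Document(doc_id, text, sentences, entities, events)
    return doc, gold


def generate(config: GeneratorConfig
             ) -> tuple[list[Document], FixtureBackend, list[GoldRecord]]:
    """Generate a corpus: documents, exact fixture parses, gold records.

    Fully reproducible from ``config.seed``; identical configs produce
    byte-identical corpora.
    """
    config.validate()
    lexicon = load_lexicon(config.cue_inventory)
    lex_lemmas = frozenset(l for e in lexicon.entries for l in e.lemma_sequence)
    rng = np.random.default_rng(config.seed)
    specs = [_draw_sentence(rng, config, lex_lemmas) for _ in range(config.n_sentences)]

    backend = FixtureBackend()
    docs: list[Document] = []
    gold: list[GoldRecord] = []
    spd = max(1, config.sentences_per_doc)
    for d, lo in enumerate(range(0, len(specs), spd)):
        chunk = specs[lo : lo + spd]
        doc, g = _assemble_document(f"D{d + 1:05d}", chunk)
        docs.append(doc)
        gold.extend(g)
        for spec in chunk:
            backend.add(spec.text, spec.parse)
    return docs, backend, gold


def gold_split(records: list[GoldRecord], train_fraction: float, seed: int
               ) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test split of event keys, stratified by
    polarity, seeded."""
    if not 0.0 < train_fraction < 1.0:
        raise NegevError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for pol in (POSITIVE, NEGATED):
        keys = [r.key for r in records if r.polarity == pol]
        order = rng.permutation(len(keys))
        n_train = int(round(train_fraction * len(keys)))
        for rank, i in enumerate(order):
            (train if rank < n_train else test).append(keys[int(i)])
    return sorted(train), sorted(test)
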