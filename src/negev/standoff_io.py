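"""Bio-event data model and BioNLP-ST-style standoff I/O.

A *bio-event* is a structured representation of a biological action or
relation: a trigger span anchoring the event in text, an event type, a set
of role-labelled participants (entities or nested events), optional
attributes such as location, and a polarity flag — ``positive`` when the
event is asserted and ``negated`` when the text asserts its non-existence.

Documents travel as the standard standoff triple: the raw text (``.txt``,
one sentence per line), the given entities (``.a1``, T-records) and the
event layer (``.a2``: trigger T-records, E-records, and M-records such as
``M1 Negation E2`` flagging negated events).  All character offsets are
0-based half-open.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Union

from .errors import IntegrityError, ResolutionError, StructureError

POSITIVE = "positive"
NEGATED = "negated"

# the 9 BioNLP'09 shared-task event classes
BIONLP_EVENT_TYPES = (
    "gene_expression",
    "transcription",
    "protein_catabolism",
    "phosphorylation",
    "localization",
    "binding",
    "regulation",
    "positive_regulation",
    "negative_regulation",
)


@dataclass(frozen=True)
class TextSpan:
    """A character span with its surface string; 0-based, half-open."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class Entity:
    id: str
    semantic_type: str
    span: TextSpan


@dataclass
class Participant:
    """A role-labelled slot filler: an entity or a nested event."""

    role: str
    filler: Union["Entity", "BioEvent"]


@dataclass
class BioEvent:
    id: str
    event_type: str
    trigger: TextSpan
    participants: list[Participant] = field(default_factory=list)
    attributes: dict[str, Entity] = field(default_factory=dict)
    polarity: str = POSITIVE
    modifications: list[str] = field(default_factory=list)  # e.g. Speculation

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATED):
            raise ValueError(f"polarity must be positive|negated, got {self.polarity!r}")


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[TextSpan]
    entities: list[Entity]
    events: list[BioEvent]

    def sentence_index_of(self, span: TextSpan) -> int:
        """Index of the sentence containing ``span`` (by its start offset).

        Events straddling sentence boundaries are aligned to the sentence
        containing their trigger, so features are always computed relative
        to the trigger's sentence.
        """
        for i, sent in enumerate(self.sentences):
            if sent.start <= span.start < sent.end:
                return i
        raise ResolutionError(
            f"{self.doc_id}: span [{span.start},{span.end}) lies in no sentence"
        )


def is_complex(event: BioEvent) -> bool:
    """True iff any participant of the event is itself a bio-event."""
    return any(isinstance(p.filler, BioEvent) for p in event.participants)


def validate(doc: Document) -> None:
    """Check all document invariants; raise on the first violation."""
    seen_ids: set[str] = set()
    for ent in doc.entities:
        if ent.id in seen_ids:
            raise IntegrityError(f"{doc.doc_id}: duplicate id {ent.id}")
        seen_ids.add(ent.id)
        _check_span(doc, ent.span, ent.id)
    for ev in doc.events:
        if ev.id in seen_ids:
            raise IntegrityError(f"{doc.doc_id}: duplicate id {ev.id}")
        seen_ids.add(ev.id)
        _check_span(doc, ev.trigger, ev.id)
        for ent in ev.attributes.values():
            _check_span(doc, ent.span, ent.id)
    _check_acyclic(doc.events)
    # sentence spans: ordered, non-overlapping
    for a, b in zip(doc.sentences, doc.sentences[1:]):
        if a.end > b.start:
            raise IntegrityError(f"{doc.doc_id}: overlapping sentence spans")


def _check_span(doc: Document, span: TextSpan, owner: str) -> None:
    actual = doc.text[span.start : span.end]
    if actual != span.text:
        raise IntegrityError(
            f"{doc.doc_id}/{owner}: span text {span.text!r} != document slice {actual!r}"
        )


def _check_acyclic(events: Iterable[BioEvent]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    state: dict[int, int] = {}

    def visit(ev: BioEvent) -> None:
        s = state.get(id(ev), WHITE)
        if s == GREY:
            raise StructureError(f"cyclic event nesting through {ev.id}")
        if s == BLACK:
            return
        state[id(ev)] = GREY
        for p in ev.participants:
            if isinstance(p.filler, BioEvent):
                visit(p.filler)
        state[id(ev)] = BLACK

    for ev in events:
        visit(ev)


# ---------------------------------------------------------------------------
# standoff parsing / serialization

_T_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_RE = re.compile(r"^(E\d+)\t(.*)$")
_M_RE = re.compile(r"^(M\d+)\t(\S+) (E\d+)$")

_LOCATION_ARGS = {"AtLoc", "ToLoc", "Loc", "Location"}


def _sentences_from_text(text: str) -> list[TextSpan]:
    """One sentence per text line (the convention used throughout)."""
    spans = []
    pos = 0
    for line in text.split("\n"):
        if line:
            spans.append(TextSpan(pos, pos + len(line), line))
        pos += len(line) + 1
    return spans


def read_standoff(text_content: str, entity_lines: str, event_lines: str) -> Document:
    """Parse a standoff triple into a :class:`Document`.

    ``entity_lines`` holds the given entities (T-records); ``event_lines``
    holds trigger T-records, E-records and M-records.  ``M# Negation E#``
    sets the referenced event's polarity to ``negated``; other modification
    types (e.g. Speculation) are preserved on the event but otherwise
    ignored.
    """
    entities: dict[str, Entity] = {}
    triggers: dict[str, tuple[str, TextSpan]] = {}  # id -> (type, span)
    for lines, is_a1 in ((entity_lines, True), (event_lines, False)):
        for raw in lines.splitlines():
            raw = raw.rstrip("\n")
            if not raw or not raw.startswith("T"):
                continue
            m = _T_RE.match(raw)
            if m is None:
                raise IntegrityError(f"malformed T-record: {raw!r}")
            tid, ttype, start, end, surface = m.groups()
            span = TextSpan(int(start), int(end), surface)
            if text_content[span.start : span.end] != surface:
                raise IntegrityError(
                    f"{tid}: surface {surface!r} != text slice "
                    f"{text_content[span.start:span.end]!r}"
                )
            if is_a1:
                entities[tid] = Entity(tid, ttype, span)
            else:
                triggers[tid] = (ttype, span)

    # first pass: create shells so E-records can reference one another
    raw_events: dict[str, str] = {}
    for raw in event_lines.splitlines():
        m = _E_RE.match(raw)
        if m:
            raw_events[m.group(1)] = m.group(2)

    events: dict[str, BioEvent] = {}
    for eid, body in raw_events.items():
        head, *_ = body.split(" ")
        etype, _, trig_id = head.partition(":")
        if trig_id not in triggers:
            raise ResolutionError(f"{eid}: trigger {trig_id!r} not found")
        ttype, tspan = triggers[trig_id]
        events[eid] = BioEvent(eid, etype, tspan)

    for eid, body in raw_events.items():
        ev = events[eid]
        args = body.split(" ")[1:]
        for arg in args:
            role, _, ref = arg.partition(":")
            if ref in entities:
                filler: Union[Entity, BioEvent] = entities[ref]
            elif ref in events:
                filler = events[ref]
            else:
                raise ResolutionError(f"{eid}: argument {ref!r} not found")
            if role in _LOCATION_ARGS:
                if not isinstance(filler, Entity):
                    raise ResolutionError(f"{eid}: location {ref!r} is not an entity")
                ev.attributes["location"] = filler
            else:
                ev.participants.append(Participant(role.rstrip("0123456789").lower(), filler))

    for raw in event_lines.splitlines():
        m = _M_RE.match(raw)
        if m is None:
            continue
        _, mtype, target = m.groups()
        if target not in events:
            raise ResolutionError(f"M-record targets unknown event {target!r}")
        if mtype == "Negation":
            events[target].polarity = NEGATED
        else:
            events[target].modifications.append(mtype)

    doc = Document(
        doc_id="doc",
        text=text_content,
        sentences=_sentences_from_text(text_content),
        entities=list(entities.values()),
        events=[events[k] for k in sorted(events, key=lambda e: int(e[1:]))],
    )
    validate(doc)
    return doc


def write_standoff(doc: Document) -> tuple[str, str]:
    """Serialize a document back to ``(.a1 contents, .a2 contents)``.

    Record ids are regenerated; triggers continue the T numbering after the
    a1 entities, per the shared-task convention.  Each negated event yields
    exactly one ``M# Negation E#`` line.
    """
    validate(doc)
    a1: list[str] = []
    ent_ids: dict[int, str] = {}
    counter = 0
    for ent in doc.entities:
        counter += 1
        tid = f"T{counter}"
        ent_ids[id(ent)] = tid
        a1.append(f"{tid}\t{ent.semantic_type} {ent.span.start} {ent.span.end}\t{ent.span.text}")

    a2: list[str] = []
    trig_ids: dict[tuple[str, int, int], str] = {}
    for ev in doc.events:
        key = (ev.event_type, ev.trigger.start, ev.trigger.end)
        if key not in trig_ids:
            counter += 1
            trig_ids[key] = f"T{counter}"
            a2.append(
                f"T{counter}\t{ev.event_type} {ev.trigger.start} {ev.trigger.end}\t{ev.trigger.text}"
            )

    ev_ids = {id(ev): f"E{i + 1}" for i, ev in enumerate(doc.events)}
    for ev in doc.events:
        parts = [f"{ev.event_type}:{trig_ids[(ev.event_type, ev.trigger.start, ev.trigger.end)]}"]
        role_counts: dict[str, int] = {}
        for p in ev.participants:
            label = p.role.capitalize()
            n = role_counts.get(p.role, 0)
            role_counts[p.role] = n + 1
            if n:
                label = f"{label}{n + 1}"
            if isinstance(p.filler, BioEvent):
                parts.append(f"{label}:{ev_ids[id(p.filler)]}")
            else:
                if id(p.filler) not in ent_ids:
                    raise ResolutionError(
                        f"{ev.id}: participant entity {p.filler.id} not in document"
                    )
                parts.append(f"{label}:{ent_ids[id(p.filler)]}")
        for role, ent in sorted(ev.attributes.items()):
            if id(ent) not in ent_ids:
                raise ResolutionError(f"{ev.id}: attribute entity {ent.id} not in document")
            label = "AtLoc" if role == "location" else role.capitalize()
            parts.append(f"{label}:{ent_ids[id(ent)]}")
        a2.append(f"{ev_ids[id(ev)]}\t{' '.join(parts)}")

    m_counter = 0
    for ev in doc.events:
        if ev.polarity == NEGATED:
            m_counter += 1
            a2.append(f"M{m_counter}\tNegation {ev_ids[id(ev)]}")
        for mod in ev.modifications:
            m_counter += 1
            a2.append(f"M{m_counter}\t{mod} {ev_ids[id(ev)]}")

    return "\n".join(a1) + ("\n" if a1 else ""), "\n".join(a2) + ("\n" if a2 else "")


# ---------------------------------------------------------------------------
# structural equality (ignores record ids, which are regenerated on write)

def structural_signature(doc: Document):
    """A canonical, id-free form of the document, for round-trip equality."""

    def ent_sig(ent: Entity):
        return ("entity", ent.semantic_type, ent.span.start, ent.span.end, ent.span.text)

    def ev_sig(ev: BioEvent):
        return (
            "event",
            ev.event_type,
            (ev.trigger.start, ev.trigger.end, ev.trigger.text),
            tuple(
                sorted(
                    (p.role, ev_sig(p.filler) if isinstance(p.filler, BioEvent) else ent_sig(p.filler))
                    for p in ev.participants
                )
            ),
            tuple(sorted((role, ent_sig(e)) for role, e in ev.attributes.items())),
            ev.polarity,
            tuple(sorted(ev.modifications)),
        )

    return (
        doc.text,
        tuple((s.start, s.end) for s in doc.sentences),
        tuple(sorted(ent_sig(e) for e in doc.entities)),
        tuple(sorted(ev_sig(e) for e in doc.events)),
    )


def corpus_stats(docs: Iterable[Document]) -> dict:
    """Event totals and the negation percentage over a corpus.

    The percentage is ``100 * negated / total`` rounded to one decimal; it
    is ``None`` (reported as undefined, never 0) when the corpus holds no
    events.
    """
    total = 0
    negated = 0
    for doc in docs:
        for ev in doc.events:
            total += 1
            if ev.polarity == NEGATED:
                negated += 1
    pct = round(100.0 * negated / total, 1) if total else None
    return {"total_events": total, "negated_events": negated, "negation_percentage": pct}


# ---------------------------------------------------------------------------
# portable JSON serialization (fixtures, generator output)

def document_to_dict(doc: Document) -> dict:
    ent_index = {id(e): i for i, e in enumerate(doc.entities)}
    ev_index = {id(e): i for i, e in enumerate(doc.events)}

    def span(s: TextSpan):
        return [s.start, s.end, s.text]

    def ref(filler):
        if isinstance(filler, BioEvent):
            return ["event", ev_index[id(filler)]]
        return ["entity", ent_index[id(filler)]]

    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "sentences": [span(s) for s in doc.sentences],
        "entities": [
            {"id": e.id, "semantic_type": e.semantic_type, "span": span(e.span)}
            for e in doc.entities
        ],
        "events": [
            {
                "id": e.id,
                "event_type": e.event_type,
                "trigger": span(e.trigger),
                "participants": [[p.role, ref(p.filler)] for p in e.participants],
                "attributes": {r: ent_index[id(ent)] for r, ent in e.attributes.items()},
                "polarity": e.polarity,
                "modifications": list(e.modifications),
            }
            for e in doc.events
        ],
    }


def document_from_dict(data: dict) -> Document:
    def span(triple) -> TextSpan:
        return TextSpan(triple[0], triple[1], triple[2])

    entities = [Entity(d["id"], d["semantic_type"], span(d["span"])) for d in data["entities"]]
    events = [
        BioEvent(d["id"], d["event_type"], span(d["trigger"]), [], {}, d["polarity"],
                 list(d.get("modifications", [])))
        for d in data["events"]
    ]
    for ev, d in zip(events, data["events"]):
        for role, (kind, idx) in d["participants"]:
            ev.participants.append(
                Participant(role, events[idx] if kind == "event" else entities[idx])
            )
        for role, idx in d["attributes"].items():
            ev.attributes[role] = entities[idx]
    doc = Document(
        doc_id=data["doc_id"],
        text=data["text"],
        sentences=[span(s) for s in data["sentences"]],
        entities=entities,
        events=events,
    )
    validate(doc)
    return doc


def document_to_json(doc: Document) -> str:
    return json.dumps(document_to_dict(doc), indent=None, sort_keys=True)


def document_from_json(payload: str) -> Document:
    return document_from_dict(json.loads(payload))
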