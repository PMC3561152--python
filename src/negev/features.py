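"""Feature extraction for event-polarity classification.

One row is produced per (bio-event, parsed sentence) pair, combining six
groups of engineered features:

* **syntactic** — POS tags of the head tokens of the trigger, first theme,
  first cause and the negation cue;
* **semantic** — the event type, the set of participant roles and
  semantic types present, and whether the event is *complex* (has an
  event-valued participant);
* **lexical** — cue presence, the cue's identity, and whether a
  deactivated cue occurs in the sentence plus the deactivator's position
  relative to its cue;
* **lexico-semantic** — token distances from the cue to the trigger and
  to the location attribute, whether the cue sits inside the trigger
  span, and whether it precedes the trigger;
* **dependency** — existence of direct/indirect dependency relations
  between cue and trigger (and cue and location), the first relation
  label on the path, and the chain length;
* **constituency** — S-, VP- and NP-command between cue and trigger (and
  cue and location), and whether the trigger / any participant / the
  location fall inside the cue's syntactic scope.

Every row carries the full, fixed feature-name set; absent information is
encoded with sentinels (``NONE`` for categoricals, ``-1`` for distances,
``False`` for flags), never by dropping keys.  When a sentence holds
several active cues, the one whose head token is nearest the trigger head
is used (leftmost on ties); deactivated cues never drive cue features but
do drive the deactivator features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import parse_layer as pl
from .cue_lexicon import CueLexicon, CueMatch, apply_deactivation, match_cues
from .errors import AlignmentError, SchemaError
from .standoff_io import NEGATED, BioEvent, Document, Entity, is_complex

NONE = "NONE"

#: feature name -> kind ("cat" | "bool" | "int" | "set"), grouped
FEATURE_GROUPS: dict[str, dict[str, str]] = {
    "syntactic": {
        "pos_trigger": "cat",
        "pos_theme": "cat",
        "pos_cause": "cat",
        "pos_cue": "cat",
    },
    "semantic": {
        "event_type": "cat",
        "roles_present": "set",
        "participant_types": "set",
        "is_complex": "bool",
    },
    "lexical": {
        "cue_present": "bool",
        "cue_id": "cat",
        "deactivator_present": "bool",
        "deactivator_relpos": "cat",
    },
    "lexico_semantic": {
        "dist_cue_trigger": "int",
        "dist_cue_location": "int",
        "cue_in_trigger": "bool",
        "cue_precedes_trigger": "bool",
    },
    "dependency": {
        "dep_direct_cue_trigger": "bool",
        "dep_connected_cue_trigger": "bool",
        "dep_first_label_cue_trigger": "cat",
        "dep_chainlen_cue_trigger": "int",
        "dep_direct_cue_location": "bool",
        "dep_connected_cue_location": "bool",
        "dep_first_label_cue_location": "cat",
        "dep_chainlen_cue_location": "int",
    },
    "constituency": {
        "s_command_cue_trigger": "bool",
        "vp_command_cue_trigger": "bool",
        "np_command_cue_trigger": "bool",
        "s_command_cue_location": "bool",
        "vp_command_cue_location": "bool",
        "np_command_cue_location": "bool",
        "scope_has_trigger": "bool",
        "scope_has_participant": "bool",
        "scope_has_location": "bool",
    },
}

FEATURE_TYPES: dict[str, str] = {
    name: kind for group in FEATURE_GROUPS.values() for name, kind in group.items()
}
FEATURE_NAMES: tuple[str, ...] = tuple(sorted(FEATURE_TYPES))

_SENTINEL = {"cat": NONE, "bool": False, "int": -1, "set": frozenset()}


@dataclass
class FeatureVector:
    event_id: str
    features: dict
    gold_polarity: Optional[str] = None


def select_cue(
    cues: Sequence[CueMatch], event: BioEvent, parse: pl.ParseResult,
    sentence_offset: int = 0,
) -> Optional[CueMatch]:
    """The active cue nearest the trigger head, leftmost on ties; ``None``
    when the sentence holds no active (non-deactivated) cue."""
    active = [c for c in cues if not c.deactivated]
    if not active:
        return None
    trig_head = _head_of_span(parse, event.trigger.start - sentence_offset,
                              event.trigger.end - sentence_offset)
    return min(active, key=lambda c: (abs(_cue_head(c, parse) - trig_head), c.start))


def _cue_head(cue: CueMatch, parse: pl.ParseResult) -> int:
    return pl.span_head(cue.start, cue.end + 1, parse)


def _head_of_span(parse: pl.ParseResult, start: int, end: int) -> int:
    first, last = pl.char_span_to_tokens(parse, start, end)
    return pl.span_head(first, last + 1, parse)


def _participant_span(filler) -> tuple[int, int]:
    if isinstance(filler, BioEvent):
        # a nested event has no entity span; its trigger stands in
        return (filler.trigger.start, filler.trigger.end)
    return (filler.span.start, filler.span.end)


def extract(
    event: BioEvent,
    parse: pl.ParseResult,
    cues: Sequence[CueMatch],
    sentence_offset: int = 0,
) -> FeatureVector:
    """Compute the full feature vector for one event in its sentence.

    ``sentence_offset`` is the character offset of the sentence within the
    document, so document-level spans can be aligned to sentence tokens.
    """
    off = sentence_offset
    f: dict = {name: _SENTINEL[kind] for name, kind in FEATURE_TYPES.items()}

    try:
        trig_first, trig_last = pl.char_span_to_tokens(
            parse, event.trigger.start - off, event.trigger.end - off
        )
    except AlignmentError as exc:
        raise AlignmentError(f"{event.id}: trigger not alignable: {exc}") from exc
    trig_head = pl.span_head(trig_first, trig_last + 1, parse)

    f["pos_trigger"] = parse.tokens[trig_head].pos
    f["event_type"] = event.event_type
    f["roles_present"] = frozenset(p.role for p in event.participants)
    f["participant_types"] = frozenset(
        p.filler.event_type if isinstance(p.filler, BioEvent) else p.filler.semantic_type
        for p in event.participants
    )
    f["is_complex"] = is_complex(event)

    def head_of(filler) -> Optional[int]:
        s, e = _participant_span(filler)
        try:
            return _head_of_span(parse, s - off, e - off)
        except AlignmentError:
            return None  # participant outside the trigger's sentence

    for role, feat in (("theme", "pos_theme"), ("cause", "pos_cause")):
        for p in event.participants:
            if p.role == role:  # first participant in annotation order
                h = head_of(p.filler)
                if h is not None:
                    f[feat] = parse.tokens[h].pos
                break

    location: Optional[Entity] = event.attributes.get("location")
    loc_head: Optional[int] = None
    if location is not None:
        loc_head = head_of(location)

    # deactivator features come from any deactivated match, independently
    # of which cue (if any) drives the cue features
    deact = [c for c in cues if c.deactivated]
    if deact:
        f["deactivator_present"] = True
        # the deactivation pattern is "not <deactivator>": the deactivator
        # always follows its cue
        f["deactivator_relpos"] = "after"

    cue = select_cue(cues, event, parse, sentence_offset=off)
    if cue is None:
        return FeatureVector(event.id, f, event.polarity)

    cue_head = _cue_head(cue, parse)
    f["cue_present"] = True
    f["cue_id"] = cue.entry.display_name
    f["pos_cue"] = parse.tokens[cue_head].pos
    f["cue_in_trigger"] = trig_first <= cue.start and cue.end <= trig_last
    f["dist_cue_trigger"] = 0 if f["cue_in_trigger"] else abs(cue_head - trig_head)
    f["cue_precedes_trigger"] = cue.start < trig_first

    path = pl.dep_path(cue_head, trig_head, parse)
    f["dep_connected_cue_trigger"] = path.exists and path.length > 0
    f["dep_direct_cue_trigger"] = path.direct
    if path.exists and path.labels:
        f["dep_first_label_cue_trigger"] = path.labels[0]
        f["dep_chainlen_cue_trigger"] = path.length

    for cat, feat in (("S", "s_command_cue_trigger"), ("VP", "vp_command_cue_trigger"),
                      ("NP", "np_command_cue_trigger")):
        if cue_head != trig_head:
            f[feat] = pl.commands(cue_head, trig_head, cat, parse)

    if loc_head is not None:
        f["dist_cue_location"] = abs(cue_head - loc_head)
        lpath = pl.dep_path(cue_head, loc_head, parse)
        f["dep_connected_cue_location"] = lpath.exists and lpath.length > 0
        f["dep_direct_cue_location"] = lpath.direct
        if lpath.exists and lpath.labels:
            f["dep_first_label_cue_location"] = lpath.labels[0]
            f["dep_chainlen_cue_location"] = lpath.length
        for cat, feat in (("S", "s_command_cue_location"),
                          ("VP", "vp_command_cue_location"),
                          ("NP", "np_command_cue_location")):
            if cue_head != loc_head:
                f[feat] = pl.commands(cue_head, loc_head, cat, parse)

    lo, hi = pl.cue_scope(cue, parse)
    f["scope_has_trigger"] = lo <= trig_head <= hi
    part_heads = [h for h in (head_of(p.filler) for p in event.participants) if h is not None]
    f["scope_has_participant"] = any(lo <= h <= hi for h in part_heads)
    if loc_head is not None:
        f["scope_has_location"] = lo <= loc_head <= hi

    return FeatureVector(event.id, f, event.polarity)


def featurize_document(
    doc: Document, backend: pl.ParserBackend, lexicon: CueLexicon
) -> list[FeatureVector]:
    """Feature rows for every event in a document (trigger-sentence aligned)."""
    rows: list[FeatureVector] = []
    parse_cache: dict[int, tuple[pl.ParseResult, list[CueMatch]]] = {}
    for ev in doc.events:
        si = doc.sentence_index_of(ev.trigger)
        if si not in parse_cache:
            sent = doc.sentences[si]
            p = pl.parse(sent.text, backend)
            cues = apply_deactivation(match_cues(p.triples(), lexicon), p.triples())
            parse_cache[si] = (p, cues)
        p, cues = parse_cache[si]
        row = extract(ev, p, cues, sentence_offset=doc.sentences[si].start)
        row.event_id = f"{doc.doc_id}/{ev.id}"
        rows.append(row)
    return rows


def featurize_corpus(
    docs: Iterable[Document], backend: pl.ParserBackend, lexicon: CueLexicon
) -> list[FeatureVector]:
    rows: list[FeatureVector] = []
    for doc in docs:
        rows.extend(featurize_document(doc, backend, lexicon))
    return rows


# ---------------------------------------------------------------------------
# vectorization

@dataclass(frozen=True)
class Column:
    feature: str
    kind: str  # "bool" | "int" | "cat" | "set"
    level: Optional[str] = None  # category level or set member

    @property
    def name(self) -> str:
        return self.feature if self.level is None else f"{self.feature}={self.level}"


def build_schema(
    rows: Sequence[FeatureVector], groups: Optional[Sequence[str]] = None
) -> list[Column]:
    """Deterministic column schema: sorted feature names, sorted levels.

    ``groups`` restricts the schema to a subset of the six feature groups
    (for ablation runs); default is all of them.
    """
    if groups is None:
        names = FEATURE_NAMES
    else:
        unknown = set(groups) - set(FEATURE_GROUPS)
        if unknown:
            raise SchemaError(f"unknown feature groups: {sorted(unknown)}")
        names = tuple(sorted(n for g in groups for n in FEATURE_GROUPS[g]))
    for row in rows:
        if set(row.features) != set(FEATURE_NAMES):
            raise SchemaError(
                f"row {row.event_id} does not carry the declared feature set"
            )
    schema: list[Column] = []
    for name in names:
        kind = FEATURE_TYPES[name]
        if kind in ("bool", "int"):
            schema.append(Column(name, kind))
        elif kind == "cat":
            levels = sorted({str(r.features[name]) for r in rows} | {NONE})
            schema.extend(Column(name, kind, lv) for lv in levels)
        else:  # set
            members = sorted({m for r in rows for m in r.features[name]})
            schema.extend(Column(name, kind, m) for m in members)
    return schema


def vectorize(
    rows: Sequence[FeatureVector], groups: Optional[Sequence[str]] = None,
    schema: Optional[list[Column]] = None,
):
    """Encode rows as a dense design matrix.

    Returns ``(X, y, schema)``: categoricals one-hot with an explicit NONE
    level, set features as membership indicators, booleans as 0/1 and
    integers passed through.  ``y`` is 1 for negated, 0 for positive, and
    ``None`` when any row lacks a gold polarity.
    """
    if schema is None:
        schema = build_schema(rows, groups)
    X = np.zeros((len(rows), len(schema)), dtype=float)
    for i, row in enumerate(rows):
        for j, col in enumerate(schema):
            val = row.features[col.feature]
            if col.kind == "bool":
                X[i, j] = 1.0 if val else 0.0
            elif col.kind == "int":
                X[i, j] = float(val)
            elif col.kind == "cat":
                X[i, j] = 1.0 if str(val) == col.level else 0.0
            else:
                X[i, j] = 1.0 if col.level in val else 0.0
    if all(r.gold_polarity is not None for r in rows) and rows:
        y = np.array([1 if r.gold_polarity == NEGATED else 0 for r in rows], dtype=int)
    else:
        y = None
    return X, y, schema


def devectorize(row: np.ndarray, schema: Sequence[Column]) -> dict:
    """Decode one design-matrix row back into a feature dict (the inverse
    of :func:`vectorize` for features covered by the schema)."""
    out: dict = {}
    sets: dict[str, set] = {}
    for val, col in zip(row, schema):
        if col.kind == "bool":
            out[col.feature] = bool(val)
        elif col.kind == "int":
            out[col.feature] = int(val)
        elif col.kind == "cat":
            if val == 1.0:
                out[col.feature] = col.level
        else:
            bucket = sets.setdefault(col.feature, set())
            if val == 1.0:
                bucket.add(col.level)
    for feat, members in sets.items():
        out[feat] = frozenset(members)
    return out
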