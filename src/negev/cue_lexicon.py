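"""Negation cue lexicons and in-sentence cue matching.

Four cue lists are packaged: ``c40`` (40 cues combining previously
published lists with corpus analysis), ``cBioScope`` (the 28 BioScope
cues), ``cBioInfer`` (25 cues annotated in BioInfer) and ``cCore`` (the
most frequent cues observed across negated bio-events; the published list
prints a size of 20 but enumerates 19 elements — the packaged lexicon
follows the printed elements).

Matching is lemma-based and case-insensitive, so inflectional variants
(*fails*, *failed*) match their citation form.  Multi-word cues
(*could not*, *with the exception of*) are matched longest-first, left to
right, and suppress matches of their sub-spans.  Entries printed with a
part-of-speech qualifier — *lack (noun)* vs. *lack (verb)* — only match
tokens tagged compatibly.

A matched *not* immediately followed by one of its deactivators (*clear*,
*evident*, *known*, *necessarily*, *only*) is flagged as deactivated
rather than dropped: deactivated matches still feed the deactivator
features downstream.  Deactivation patterns for *no*-constructions
(*no evidence of*, *no proof* ...) are deliberately NOT applied — in
biological event annotation those constructions do trigger negated
events, unlike in linguistic scope annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

from .errors import LexiconError

LEXICON_NAMES = ("c40", "cBioScope", "cBioInfer", "cCore")

#: printed sizes of the four cue lists (cCore prints 20 but lists 19)
DECLARED_SIZES = {"c40": 40, "cBioScope": 28, "cBioInfer": 25, "cCore": 20}

#: words cancelling an immediately preceding "not"
NOT_DEACTIVATORS = frozenset({"clear", "evident", "known", "necessarily", "only"})

_NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS", "NOUN", "PROPN"}
_VERB_TAGS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ", "MD", "VERB", "AUX"}


@dataclass(frozen=True)
class CueEntry:
    """One cue-list entry: a lemma sequence plus optional POS constraint."""

    lemma_sequence: tuple[str, ...]
    pos_constraint: Optional[str] = None  # "noun" | "verb" | None

    @property
    def display_name(self) -> str:
        name = " ".join(self.lemma_sequence)
        if self.pos_constraint:
            name += f" ({self.pos_constraint})"
        return name


@dataclass(frozen=True)
class CueLexicon:
    name: str
    entries: tuple[CueEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CueMatch:
    entry: CueEntry
    token_indices: tuple[int, ...]  # contiguous sentence positions
    deactivated: bool = False

    @property
    def start(self) -> int:
        return self.token_indices[0]

    @property
    def end(self) -> int:
        return self.token_indices[-1]


def _parse_lexicon_text(name: str, text: str) -> CueLexicon:
    entries: list[CueEntry] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "|" in line:
            lemmas, _, pos = line.partition("|")
            entry = CueEntry(tuple(lemmas.strip().lower().split()), pos.strip())
        else:
            entry = CueEntry(tuple(line.lower().split()))
        entries.append(entry)
    names = [e.display_name for e in entries]
    if len(set(names)) != len(names):
        raise LexiconError(f"{name}: duplicate entries")
    return CueLexicon(name, tuple(entries))


def load_lexicon(name_or_path: str) -> CueLexicon:
    """Load a packaged lexicon by name, or a custom one from a file path.

    Custom files use the same dialect as the packaged ones: one entry per
    line, lemmas separated by spaces, an optional ``|noun`` / ``|verb``
    suffix constraining the part of speech.
    """
    if name_or_path in LEXICON_NAMES:
        text = resources.files("negev.data").joinpath(f"{name_or_path}.txt").read_text()
        return _parse_lexicon_text(name_or_path, text)
    import os

    if os.path.exists(name_or_path):
        with open(name_or_path) as fh:
            return _parse_lexicon_text(os.path.basename(name_or_path), fh.read())
    raise LexiconError(
        f"unknown lexicon {name_or_path!r}; valid names: {', '.join(LEXICON_NAMES)}"
    )


def _pos_compatible(constraint: Optional[str], pos: str) -> bool:
    if constraint is None:
        return True
    if constraint == "noun":
        return pos in _NOUN_TAGS
    if constraint == "verb":
        return pos in _VERB_TAGS
    return False


def match_cues(
    tokens: Sequence[tuple[str, str, str]], lexicon: CueLexicon
) -> list[CueMatch]:
    """All maximal, non-overlapping cue matches in a ``(text, lemma, POS)`` stream.

    Longest match wins at each position, scanning left to right; a token
    consumed by a multi-word match cannot anchor a shorter one.  For
    POS-constrained entries the constraint applies to the head (first)
    lemma's token.
    """
    lemmas = [t[1].lower() for t in tokens]
    pos_tags = [t[2] for t in tokens]
    # entries grouped by first lemma, longest first; entry order irrelevant
    by_first: dict[str, list[CueEntry]] = {}
    for entry in lexicon.entries:
        by_first.setdefault(entry.lemma_sequence[0], []).append(entry)
    for group in by_first.values():
        group.sort(key=lambda e: (-len(e.lemma_sequence), e.pos_constraint or ""))

    matches: list[CueMatch] = []
    i = 0
    n = len(lemmas)
    while i < n:
        chosen: Optional[CueEntry] = None
        for entry in by_first.get(lemmas[i], ()):
            seq = entry.lemma_sequence
            if i + len(seq) <= n and tuple(lemmas[i : i + len(seq)]) == seq:
                if _pos_compatible(entry.pos_constraint, pos_tags[i]):
                    chosen = entry
                    break
        if chosen is None:
            i += 1
        else:
            width = len(chosen.lemma_sequence)
            matches.append(CueMatch(chosen, tuple(range(i, i + width))))
            i += width
    return matches


def apply_deactivation(
    matches: Iterable[CueMatch], tokens: Sequence[tuple[str, str, str]]
) -> list[CueMatch]:
    """Flag deactivated *not* matches; never add or remove matches.

    A match on the single-word entry *not* is deactivated iff the lemma of
    the immediately following token is one of the five deactivators.  All
    other matches (including *no*-constructions) pass through unchanged.
    """
    out: list[CueMatch] = []
    lemmas = [t[1].lower() for t in tokens]
    for m in matches:
        if m.entry.lemma_sequence == ("not",):
            nxt = m.end + 1
            if nxt < len(lemmas) and lemmas[nxt] in NOT_DEACTIVATORS:
                m = replace(m, deactivated=True)
        out.append(m)
    return out
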