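"""Cue lexicon fidelity, matching semantics and deactivation."""

import numpy as np
import pytest

from negev.cue_lexicon import (
    DECLARED_SIZES,
    LEXICON_NAMES,
    apply_deactivation,
    load_lexicon,
    match_cues,
)
from negev.errors import LexiconError

# the published cue lists, verbatim
PUBLISHED = {
    "c40": "absence, absent, barely, cannot, deficiency, deficient, except, "
           "exception, fail, failure, impair, inability, inactive, independent, "
           "independently, insensitive, instead, insufficient, lack (noun), "
           "lack (verb), limited, little, loss, lose, lost, low, negative, "
           "neither, never, no, none, nor, not, prevent, resistance, resistant, "
           "unable, unaffected, unchanged, without",
    "cBioScope": "absence, absent, cannot, could not, either, except, exclude, "
                 "fail, failure, favor over, impossible, instead of, lack (noun), "
                 "lack (verb), loss, miss, negative, neither, never, no, "
                 "no longer, none, not, rather than, rule out, unable, "
                 "with the exception of, without",
    "cBioInfer": "abolished, absence, cannot, defective, deficient, despite, "
                 "differ, different, differential, distinct, failure, "
                 "independent, independently, lack, negligible, neither, no, "
                 "nor, not, protected, separately, simultaneously, unable, "
                 "unlike, without",
    "cCore": "absence, fail, inability, independent, independently, "
             "insensitive, insufficient, lack (noun), lack (verb), little, "
             "neither, no, nor, not, resistant, unable, unaffected, unchanged, "
             "without",
}


@pytest.mark.parametrize("name", LEXICON_NAMES)
def test_lexicon_matches_published_list_verbatim(name):
    lex = load_lexicon(name)
    expected = sorted(s.strip() for s in PUBLISHED[name].split(","))
    assert sorted(e.display_name for e in lex.entries) == expected


@pytest.mark.parametrize("name, size", [("cBioScope", 28), ("cBioInfer", 25), ("c40", 40)])
def test_lexicon_entry_counts(name, size):
    assert len(load_lexicon(name)) == size
    assert DECLARED_SIZES[name] == size


def test_ccore_prints_twenty_but_lists_nineteen():
    # the published size for cCore disagrees with its printed elements;
    # the packaged lexicon follows the elements
    assert len(load_lexicon("cCore")) == 19
    assert DECLARED_SIZES["cCore"] == 20


def test_unknown_lexicon_name_errors_listing_valid_names():
    with pytest.raises(LexiconError, match="c40"):
        load_lexicon("c99")


def _toks(*pairs):
    """Helper: (text, pos) pairs -> (text, lemma, pos), lemma = lowercase text."""
    return [(t, t.lower(), p) for t, p in pairs]


def test_single_not_match(c40):
    toks = _toks(("Rac1", "NNP"), ("is", "VBZ"), ("not", "RB"),
                 ("required", "VBN"), ("for", "IN"), ("activation", "NN"))
    matches = match_cues(toks, c40)
    assert [m.entry.display_name for m in matches] == ["not"]
    assert matches[0].token_indices == (2,)


def test_multiword_cue_wins_over_subspan():
    lex = load_lexicon("cBioScope")
    toks = _toks(("the", "DT"), ("complex", "NN"), ("could", "MD"),
                 ("not", "RB"), ("form", "VB"))
    matches = match_cues(toks, lex)
    assert [m.entry.display_name for m in matches] == ["could not"]
    assert matches[0].token_indices == (2, 3)


def test_no_cues_empty_result(c40):
    toks = _toks(("the", "DT"), ("protein", "NN"), ("activates", "VBZ"),
                 ("the", "DT"), ("gene", "NN"))
    assert match_cues(toks, c40) == []


def test_pos_constrained_lack_noun():
    lex = load_lexicon("cCore")
    toks = _toks(("a", "DT"), ("lack", "NN"), ("of", "IN"), ("expression", "NN"))
    matches = match_cues(toks, lex)
    assert [m.entry.display_name for m in matches] == ["lack (noun)"]
    # verb-tagged "lack" must match the verb entry instead
    toks_v = _toks(("cells", "NNS"), ("lack", "VBP"), ("STAT1", "NNP"))
    assert [m.entry.display_name for m in match_cues(toks_v, lex)] == ["lack (verb)"]


def test_lemma_based_inflection_matching(c40):
    toks = [("failed", "fail", "VBD"), ("to", "to", "TO"), ("bind", "bind", "VB")]
    assert [m.entry.display_name for m in match_cues(toks, c40)] == ["fail"]


def _oracle_matches(toks, lexicon):
    """Independent oracle: enumerate every n-gram candidate, then pick
    non-overlapping ones, earliest-start first and longest at each start."""
    from negev.cue_lexicon import _pos_compatible

    lemmas = [t[1].lower() for t in toks]
    candidates = []
    for entry in lexicon.entries:
        w = len(entry.lemma_sequence)
        for i in range(len(lemmas) - w + 1):
            if tuple(lemmas[i : i + w]) == entry.lemma_sequence and _pos_compatible(
                entry.pos_constraint, toks[i][2]
            ):
                candidates.append((i, w, entry))
    candidates.sort(key=lambda c: (c[0], -c[1]))
    taken = set()
    out = []
    for i, w, entry in candidates:
        span = set(range(i, i + w))
        if span & taken:
            continue
        taken |= span
        out.append((i, w, entry.display_name))
    return sorted(out)


_VOCAB = [
    ("not", "RB"), ("no", "DT"), ("could", "MD"), ("longer", "RB"),
    ("lack", "NN"), ("lack", "VBP"), ("fail", "VB"), ("with", "IN"),
    ("the", "DT"), ("exception", "NN"), ("of", "IN"), ("except", "IN"),
    ("rather", "RB"), ("than", "IN"), ("never", "RB"), ("without", "IN"),
    ("protein", "NN"), ("binds", "VBZ"), ("gene", "NN"), ("only", "RB"),
    ("instead", "RB"), ("rule", "VB"), ("out", "RP"), ("loss", "NN"),
]


@pytest.mark.parametrize("lexname", LEXICON_NAMES)
def test_matching_agrees_with_ngram_scan_oracle(lexname):
    """On 500 random cue-dense sentences, matching equals an exhaustive
    n-gram enumeration with the longest-match, left-to-right policy."""
    lex = load_lexicon(lexname)
    rng = np.random.default_rng(2024)
    for _ in range(500 // len(LEXICON_NAMES) + 1):
        n = int(rng.integers(1, 15))
        toks = [_VOCAB[int(i)] for i in rng.integers(0, len(_VOCAB), n)]
        toks = [(t, t.lower(), p) for t, p in toks]
        got = sorted((m.start, len(m.token_indices), m.entry.display_name)
                     for m in match_cues(toks, lex))
        assert got == _oracle_matches(toks, lex)


def test_ccore_matches_subset_of_c40(c40):
    """Every cCore entry also exists in c40, so cCore's matches on any
    sentence are a subset of c40's."""
    ccore = load_lexicon("cCore")
    assert {e.display_name for e in ccore.entries} <= {e.display_name for e in c40.entries}
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(1, 12))
        toks = [_VOCAB[int(i)] for i in rng.integers(0, len(_VOCAB), n)]
        toks = [(t, t.lower(), p) for t, p in toks]
        got_core = {(m.start, m.token_indices) for m in match_cues(toks, ccore)}
        got_40 = {(m.start, m.token_indices) for m in match_cues(toks, c40)}
        # c40 may cover a core match with a longer entry starting earlier,
        # but every token matched by cCore is matched by c40
        core_toks = {i for _, span in got_core for i in span}
        c40_toks = {i for _, span in got_40 for i in span}
        assert core_toks <= c40_toks


def test_not_only_is_deactivated(c40):
    toks = _toks(("not", "RB"), ("only", "RB"), ("IL-2", "NNP"),
                 ("but", "CC"), ("also", "RB"), ("IL-4", "NNP"))
    out = apply_deactivation(match_cues(toks, c40), toks)
    (m,) = [m for m in out if m.entry.display_name == "not"]
    assert m.deactivated


def test_not_required_stays_active(c40):
    toks = _toks(("is", "VBZ"), ("not", "RB"), ("required", "VBN"),
                 ("for", "IN"), ("activation", "NN"))
    out = apply_deactivation(match_cues(toks, c40), toks)
    (m,) = out
    assert m.entry.display_name == "not" and not m.deactivated


def test_no_evidence_stays_active(c40):
    """*no*-construction deactivators are deliberately not applied: in
    event annotation, 'no evidence that ...' does negate events."""
    toks = _toks(("no", "DT"), ("evidence", "NN"), ("that", "IN"),
                 ("X", "NNP"), ("binds", "VBZ"), ("Y", "NNP"))
    out = apply_deactivation(match_cues(toks, c40), toks)
    assert [(m.entry.display_name, m.deactivated) for m in out] == [("no", False)]


def test_deactivation_preserves_match_count(c40):
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = int(rng.integers(1, 12))
        toks = [_VOCAB[int(i)] for i in rng.integers(0, len(_VOCAB), n)]
        toks = [(t, t.lower(), p) for t, p in toks]
        matches = match_cues(toks, c40)
        out = apply_deactivation(matches, toks)
        assert len(out) == len(matches)
        assert [m.token_indices for m in out] == [m.token_indices for m in matches]
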