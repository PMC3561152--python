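"""Match negation cues in tokenised sentences and apply deactivation.

Shows longest-match multi-word cues, POS-constrained entries, and the
"not <deactivator>" pattern; note that "no evidence" stays an active cue
(in event annotation such constructions do negate events).
"""

from negev import apply_deactivation, load_lexicon, match_cues

for name in ("c40", "cBioScope", "cBioInfer", "cCore"):
    lex = load_lexicon(name)
    print(f"{name}: {len(lex)} entries")

sentences = {
    "could not":    [("the", "the", "DT"), ("complex", "complex", "NN"),
                     ("could", "could", "MD"), ("not", "not", "RB"),
                     ("form", "form", "VB")],
    "lack (noun)":  [("a", "a", "DT"), ("lack", "lack", "NN"),
                     ("of", "of", "IN"), ("expression", "expression", "NN")],
    "not only":     [("not", "not", "RB"), ("only", "only", "RB"),
                     ("IL-2", "il-2", "NNP"), ("but", "but", "CC"),
                     ("also", "also", "RB"), ("IL-4", "il-4", "NNP")],
    "no evidence":  [("no", "no", "DT"), ("evidence", "evidence", "NN"),
                     ("of", "of", "IN"), ("binding", "binding", "NN")],
}

lex = load_lexicon("cBioScope")
for label, toks in sentences.items():
    matches = apply_deactivation(match_cues(toks, lex), toks)
    desc = ", ".join(
        f"{m.entry.display_name}@{m.token_indices}"
        + (" [deactivated]" if m.deactivated else "")
        for m in matches) or "(none)"
    print(f"{label:>12}: {desc}")
# A deactivated match is kept (it feeds the deactivator features) but is
# never selected as the cue driving the cue-dependent features.
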