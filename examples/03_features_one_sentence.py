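"""Extract the full feature vector for one negated event.

The sentence is "Rac1 did not activate STAT1 ." — a trigger-type negation:
the cue *not* sits one token before the trigger and modifies it directly
in the dependency graph.
"""

from negev.cue_lexicon import apply_deactivation, load_lexicon, match_cues
from negev.features import extract
from negev.synthetic_corpus import VERBS, _assemble_document, t_neg_trigger_not

spec = t_neg_trigger_not(None, ("Rac1", "STAT1"), VERBS[0])
doc, _ = _assemble_document("DOC", [spec])
print("sentence:", spec.text)

lex = load_lexicon("c40")
triples = spec.parse.triples()
cues = apply_deactivation(match_cues(triples, lex), triples)
fv = extract(doc.events[0], spec.parse, cues)
for name in sorted(fv.features):
    print(f"  {name:32s} {fv.features[name]}")
print("gold polarity:", fv.gold_polarity)
# dist_cue_trigger=1 and dep_direct_cue_trigger=True are the signature of
# a negated-trigger construction; sentinels (-1 / NONE / False) mark
# information that is absent, here the location-related features.
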