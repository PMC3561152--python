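"""Read a standoff-annotated sentence, inspect the event, write it back.

The document is the classic activation sentence: one positive_regulation
event anchored to "activates", with an operon theme and a protein cause.
"""

from negev import corpus_stats, is_complex, read_standoff, write_standoff

TEXT = "The results suggest that the narL gene product activates the nitrate reductase operon."
A1 = (
    "T1\tprotein 25 46\tthe narL gene product\n"
    "T2\toperon 57 85\tthe nitrate reductase operon\n"
)
A2 = (
    "T3\tpositive_regulation 47 56\tactivates\n"
    "E1\tpositive_regulation:T3 Theme:T2 Cause:T1\n"
)

doc = read_standoff(TEXT, A1, A2)
ev = doc.events[0]
print(f"event {ev.id}: type={ev.event_type} trigger={ev.trigger.text!r} "
      f"polarity={ev.polarity} complex={is_complex(ev)}")
for p in ev.participants:
    print(f"  {p.role}: {p.filler.span.text!r} ({p.filler.semantic_type})")

print("corpus stats:", corpus_stats([doc]))
a1, a2 = write_standoff(doc)
print("--- regenerated .a2 ---")
print(a2, end="")
# A negated event would additionally carry one "M<k> Negation E<j>" line.
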