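absence
absent
cannot
could not
either
except
exclude
fail
failure
favor over
impossible
instead of
lack|noun
lack|verb
loss
miss
negative
neither
never
no
no longer
none
not
rather than
rule out
unable
with the exception of
without
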