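absence
absent
barely
cannot
deficiency
deficient
except
exception
fail
failure
impair
inability
inactive
independent
independently
insensitive
instead
insufficient
lack|noun
lack|verb
limited
little
loss
lose
lost
low
negative
neither
never
no
none
nor
not
prevent
resistance
resistant
unable
unaffected
unchanged
without
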