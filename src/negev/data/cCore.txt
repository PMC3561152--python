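absence
fail
inability
independent
independently
insensitive
insufficient
lack|noun
lack|verb
little
neither
no
nor
not
resistant
unable
unaffected
unchanged
without
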