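abolished
absence
cannot
defective
deficient
despite
differ
different
differential
distinct
failure
independent
independently
lack
negligible
neither
no
nor
not
protected
separately
simultaneously
unable
unlike
without
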