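# Tokens treated as one polyketide class for pair matching.  The first
# non-comment row is the class token itself; remaining rows are the
# other members.  One token per line.
pk
mal
mmal
ohmal
emal
mxmal
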