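a
ah
an
eh
er
erm
hm
hmm
huh
mhm
mm
oh
that
the
these
this
those
uh
uhhuh
um
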