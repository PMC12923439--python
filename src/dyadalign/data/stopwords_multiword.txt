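how's it going
how is it going
what's up
what is up
good morning
good afternoon
good evening
good night
nice to meet you
thank you
uh huh
um hm
uh hm
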