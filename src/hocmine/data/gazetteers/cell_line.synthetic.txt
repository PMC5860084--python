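hela
a549
mcf-7
hct116
hek293
jurkat
u2os
ht-29
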