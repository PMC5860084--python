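p53
p21
p16
kras
egfr
vegf
vegf-a
akt
mmp-9
bcl-2
caspase-3
tp53
brca1
pcna
ki-67
gapdh
tbp
stat3
nf-kb
pten
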