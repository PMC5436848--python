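# Chothia numbering, heavy chains.
# H1 = 26-32 (7 base; loops of length 8-9 carry insertion codes at the H31
# anchor, i.e. the 31/31A convention), H2 = 52-55 (4 base), H3 = 95-102.
region,start,end,label_start,anchor
FR1,1,25,1,
CDR1,26,32,26,31
FR2,33,51,33,
CDR2,52,55,52,53
FR3,56,94,56,
CDR3,95,102,95,100
FR4,103,113,103,
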