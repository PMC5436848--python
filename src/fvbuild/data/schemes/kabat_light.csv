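# Kabat numbering, light chains. L2 extends to 7 base residues (50-56).
region,start,end,label_start,anchor
FR1,1,23,1,
CDR1,24,34,24,30
FR2,35,49,35,
CDR2,50,56,50,53
FR3,57,88,57,
CDR3,89,97,89,95
FR4,98,107,98,
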