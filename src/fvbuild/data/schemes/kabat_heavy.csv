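# Kabat numbering, heavy chains. H1 = 31-35, H2 = 50-58.
region,start,end,label_start,anchor
FR1,1,30,1,
CDR1,31,35,31,33
FR2,36,49,36,
CDR2,50,58,50,54
FR3,59,94,59,
CDR3,95,102,95,100
FR4,103,113,103,
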