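# Honegger (AHo-style) numbering, heavy chains.
region,start,end,label_start,anchor
FR1,1,25,1,
CDR1,26,35,26,30
FR2,36,50,40,
CDR2,51,58,56,60
FR3,59,92,66,
CDR3,93,102,105,109
FR4,103,113,120,
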