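# Honegger (AHo-style) numbering, light chains. L2 spans 12 base residues.
region,start,end,label_start,anchor
FR1,1,23,1,
CDR1,24,34,24,29
FR2,35,46,40,
CDR2,47,58,52,57
FR3,59,88,66,
CDR3,89,97,107,111
FR4,98,107,120,
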