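# IMGT-style numbering, heavy chains (gapped monotone label map, see light table).
region,start,end,label_start,anchor
FR1,1,25,1,
CDR1,26,33,27,30
FR2,34,50,39,
CDR2,51,57,56,59
FR3,58,92,66,
CDR3,93,102,105,109
FR4,103,113,118,
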