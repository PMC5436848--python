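# IMGT-style numbering, light chains. Labels follow a gapped monotone map into
# the IMGT coordinate ranges (CDR1 from 27, CDR2 from 56, CDR3 from 105); the
# map is a curated desk-scale approximation of the published scheme.
region,start,end,label_start,anchor
FR1,1,25,1,
CDR1,26,33,27,30
FR2,34,49,39,
CDR2,50,52,56,57
FR3,53,88,62,
CDR3,89,97,105,109
FR4,98,107,118,
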