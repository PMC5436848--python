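# Chothia numbering, light chains (kappa and lambda share the table).
# CDR bounds follow the loop-length conventions used throughout this package:
# L1 = 24-34 (11 base), L2 = 50-52 (3 base), L3 = 89-97 (9 base).
# Insertion codes accumulate at the anchor label of each CDR.
region,start,end,label_start,anchor
FR1,1,23,1,
CDR1,24,34,24,30
FR2,35,49,35,
CDR2,50,52,50,51
FR3,53,88,53,
CDR3,89,97,89,95
FR4,98,107,98,
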