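# Default Chothia canonical-class definitions (Chothia scheme positions).
# Built from the canonical-structure literature at desk scale; the table is
# data, not code, and can be swapped for a site-specific curation (several
# classes, notably kL1:2A and kL2:1, are known to be restrictive in the
# residues they demand at key positions).
# constraints: semicolon-separated scheme_position:allowed_residues pairs;
# positions may lie inside the loop or in the framework (canonical classes
# depend on both, e.g. kL2:1 on Ile/Val 48 and Gly 64, kL1:2A/2B on residue 2).
class_label,chain_type,cdr_label,loop_length,constraints
kL1:1,kappa,L1,11,29:ILV;33:LM
kL1:2A,kappa,L1,7,2:I
kL1:2B,kappa,L1,7,2:L
kL1:3,kappa,L1,9,29:ILV
kL1:4,kappa,L1,12,30:LV
kL2:1,kappa,L2,3,48:IV;64:G
kL3:1,kappa,L3,9,90:QNH;95:P
kL3:2,kappa,L3,8,90:QNH
lL1:1,lambda,L1,11,25:G
lL2:1,lambda,L2,3,48:IV
lL3:1,lambda,L3,9,90:AS
H1:1,heavy,H1,7,26:G
H1:2,heavy,H1,8,26:G
H1:3,heavy,H1,9,26:G
H2:1,heavy,H2,3,71:RK
H2:2,heavy,H2,4,71:AVL
H2:3,heavy,H2,4,71:RK
H2:4,heavy,H2,6,71:RK
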