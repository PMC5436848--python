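>kappa curated variable-domain reference profile (107 base positions)
DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIYAASTLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYCQQSYSTPLTFGQGTKVEIK
>lambda curated variable-domain reference profile (107 base positions)
QSVLTQPPSVSAGTPGQRVTISCSGSSSNIGNNYWYQQLPGTAPKLLIYRNNQRPSGVPDRFSGSKSGTSATLAITGLQAEDEADYYCAAWDDSLNGFGGGTKLTVL
>heavy curated variable-domain reference profile (113 base positions)
EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGTYYADSVKGRFTISDRNSKNTLYLQMNSLRAEDTAVYYCARDRGFDYWGQGTLVTVSS
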