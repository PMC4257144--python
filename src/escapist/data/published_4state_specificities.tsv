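# provenance	published per-target specificities on the 4state_reduced decoy benchmark
PDB	NRES	NSTRUCTURES	SPECIFICITY
2CRO	65	675	0.8
3ICB	75	654	0.9
4RXN	54	677	0.9
4PTI	118	688	1
1CTF	131	631	1
1R69	97	676	1
1SN3	65	661	1
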