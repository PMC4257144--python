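# provenance	published reference C-beta EPD template, 16-pair excerpt
# learning_set	1000 PISCES chains (20% identity, 1.6 A resolution, R-factor 0.25 cutoffs)
# backend	pdb2pqr+apbs (solute dielectric 2, solvent 78, probe 1.4 A, 298 K, no salt)
# mode	CB	CB
PAIR	MEAN	SD	N
DF	-108.9	29.5	481
DY	-107.4	30.7	442
DH	-105.2	33.5	242
DW	-104.1	27.7	209
EH	-98.5	28.5	200
EY	-96.5	28	378
EW	-94.2	29.8	184
SY	-93.5	27.5	403
EF	-93.1	27.6	439
TY	-93	28.6	384
TW	-90.8	28.7	144
SW	-89.2	27.7	169
FT	89.2	26.8	436
FS	92.3	28.4	453
HS	93.7	31.8	235
HT	95.1	31.5	235
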