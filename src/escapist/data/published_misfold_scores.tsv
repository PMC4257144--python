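# provenance	published PDscores on the misfold decoy benchmark (correct vs incorrect structure per target)
PDB	NRES	CORRECT	INCORRECT
1CBH	36	18.7	12.6
1PPT	36	18	33.5
1FDX	54	33	30.9
5RXN	54	25.1	35
1SN3	65	20.7	30.3
2CI2	65	19.9	35.2
2CRO	65	26.7	43.4
1HIP	85	19.1	36.8
2B5C	85	22.1	34.3
2CDV	107	17.4	40.9
2SSI	107	22.6	20
1BP2	123	21	44.1
2PAZ	123	19.3	27.3
1P2P	124	28.6	29
1RN3	124	20.7	28.8
1LH1	153	18	26.2
2I1B	153	19	27.6
1REI	212	16.5	21.8
5PAD	212	18.8	32
1RHD	293	23.2	31.9
2CYP	293	21.2	35.8
2TMN	316	27.2	32.2
2TS1	317	21.3	28.2
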