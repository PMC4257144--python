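# provenance	published per-target specificities on the hg_structal decoy benchmark
PDB	NRES	NSTRUCTURES	SPECIFICITY
2PGHA	141	30	0.2
1MBS	153	30	0.5
2DHBA	141	30	0.6
1HDAB	145	30	0.9
1MYT	146	30	0.9
1HLM	158	30	0.9
1HSY	153	30	0.9
1MBA	146	30	0.9
1MYGA	153	30	0.9
1MYJA	153	30	0.9
1ASH	147	30	1
1BABB	146	30	1
1COLA	197	30	1
1CPCA	162	30	1
1ECD	136	30	1
1EMY	153	30	1
1FLP	142	30	1
1GDM	153	30	1
1HBG	147	30	1
1HBHA	142	30	1
1HBHB	146	30	1
1HDAA	141	30	1
1HLB	157	30	1
1ITHA	141	30	1
1LHT	153	30	1
2DHBB	146	30	1
2LHB	149	30	1
2PGHB	146	30	1
4SDHA	145	30	1
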