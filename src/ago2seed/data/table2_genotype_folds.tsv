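mirna	wildtype	tlr4_ko	nfkb_ko
miR-15a	2.63	-1.11	-1.10
miR-744	1.92	-2.36	-2.41
miR-1196	1.87	-1.78	-1.50
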