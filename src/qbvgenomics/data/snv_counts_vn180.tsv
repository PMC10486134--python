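region	snv_GZ21m081	snv_GZ21m120	snv_GZ21m167	nonsyn_GZ21m081	nonsyn_GZ21m120	nonsyn_GZ21m167
AC+C	44	41	43	13	13	13
PrM+M	49	47	52	3	3	5
E	125	121	123	12	11	11
NS1	125	123	124	10	10	10
NS2A	25	26	23	9	11	9
NS2B	31	35	32	11	12	11
NS3	200	205	204	17	18	18
NS4A	64	67	65	8	9	9
2K	7	6	7	1	1	1
NS4B	86	91	90	2	3	3
NS5	294	287	295	18	15	15
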