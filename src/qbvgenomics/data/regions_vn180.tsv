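region	start	end	kind
AC+C	113	520	mat_peptide
PrM+M	521	946	mat_peptide
E	947	2227	mat_peptide
NS1	2228	3406	mat_peptide
NS2A	3407	4012	mat_peptide
NS2B	4013	4450	mat_peptide
NS3	4451	6214	mat_peptide
NS4A	6215	6679	mat_peptide
2K	6680	6748	mat_peptide
NS4B	6749	7522	mat_peptide
NS5	7523	10189	mat_peptide
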