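# Per-pair coding-sequence divergence of the duplicate pairs: duplication type
# (S segmental, T tandem, Nd not determined), nonsynonymous (dN) and synonymous
# (dS) substitution rates and their printed ratio. PtXIP1;1 is a pseudogene.
pair	duplication	dN	dS	dNdS_printed	pseudogene
PtNIP1;1/PtNIP1;2	S	0.062	0.293	0.212	False
PtNIP3;1/PtNIP3;2	S	0.031	0.271	0.115	False
PtNIP3;3/PtNIP3;4	S	0.042	0.246	0.172	False
PtPIP1;1/PtPIP1;2	S	0.027	0.273	0.098	False
PtPIP1;4/PtPIP1;5	S	0.101	0.280	0.362	False
PtPIP2;1/PtPIP2;2	S	0.053	0.297	0.177	False
PtPIP2;3/PtPIP2;4	S	0.056	0.294	0.191	False
PtPIP2;5/PtPIP2;7	S	0.036	0.368	0.098	False
PtPIP2;5/PtPIP2;6	T	0.008	0.022	0.347	False
PtPIP2;9/PtPIP2;10	T	0.166	0.430	0.386	False
PtSIP1;1/PtSIP1;2	S	0.095	0.223	0.423	False
PtSIP1;3/PtSIP1;4	Nd	0.044	0.202	0.217	False
PtSIP2;1/PtSIP2;2	S	0.087	0.186	0.466	False
PtTIP1;1/PtTIP1;2	S	0.037	0.369	0.099	False
PtTIP1;3/PtTIP1;4	S	0.016	0.325	0.050	False
PtTIP1;5/PtTIP1;6	S	0.031	0.345	0.090	False
PtTIP1;7/PtTIP1;8	S	0.059	0.288	0.203	False
PtTIP2;1/PtTIP2;2	S	0.032	0.217	0.150	False
PtTIP2;3/PtTIP2;4	S	0.029	0.310	0.093	False
PtTIP3;1/PtTIP3;2	Nd	0.046	0.288	0.160	False
PtTIP5;1/PtTIP5;2	S	0.033	0.211	0.157	False
PtXIP1;3/PtXIP1;4	Nd	0.110	0.531	0.208	False
PtXIP1;3/PtXIP1;5	Nd	0.242	1.240	0.195	False
PtXIP1;1/PtXIP1;2	T	0.017	0.021	0.824	True
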