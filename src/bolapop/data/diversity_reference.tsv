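# published BoLA-DRB3 diversity summaries for 16 worldwide cattle cohorts
population	n	n_a	r_s	h_o	h_e	f_is	d_n	d_s
SmtCo	67	37	34	0.642	0.959	0.333	0.107	0.03
SbhCo	60	43	41.6	0.783	0.966	0.191	0.116	0.026
NorCo	111	53	38.2	0.667	0.955	0.303	0.111	0.028
MorSp	54	29	29	0.667	0.913	0.271	0.105	0.026
HolAr	413	31	20.5	0.833	0.908	0.082	0.115	0.025
HolBo	153	21	18	0.928	0.895	-0.038	0.124	0.031
HolPa	127	26	19.6	0.835	0.891	0.064	0.117	0.024
HolPe	132	19	16.6	0.902	0.886	-0.018	0.12	0.032
HolJa	101	18	15.7	0.922	0.902	-0.022	0.115	0.027
HolCh	113	21	17.2	0.841	0.893	0.059	0.113	0.028
YacBo	100	33	30.1	0.91	0.947	0.04	0.116	0.023
NeBrPe	195	33	23.5	0.759	0.855	0.113	0.116	0.027
BrPh	233	57	36.3	0.884	0.95	0.07	0.112	0.026
NeBo	116	26	21.9	0.784	0.87	0.099	0.117	0.023
NaBrPh	131	56	40.8	0.908	0.966	0.06	0.113	0.023
NaPh	480	71	36.8	0.915	0.959	0.044	0.112	0.024
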