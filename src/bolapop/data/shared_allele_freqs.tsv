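# published relative frequencies of the BoLA-DRB3 alleles shared by the
# Colombian Simbrah (N=60) and Simmental (N=67) cohorts
allele	SbhCo	SmtCo
DRB3*001:01	0.008	0.037
DRB3*002:01	0.058	0.082
DRB3*003:01	0.017	0.022
DRB3*005:01	0.025	0.06
DRB3*005:03	0.058	0.06
DRB3*009:01	0.017	0.022
DRB3*010:01	0.033	0.06
DRB3*011:01	0.025	0.022
DRB3*012:01	0.117	0.052
DRB3*013:01	0.025	0.052
DRB3*014:01:01	0.017	0.022
DRB3*016:01	0.017	0.097
DRB3*017:03	0.033	0.007
DRB3*018:01	0.017	0.015
DRB3*019:02	0.017	0.007
DRB3*020:01:01	0.025	0.007
DRB3*021:01	0.025	0.007
DRB3*026:01	0.008	0.037
DRB3*027:03	0.008	0.007
DRB3*030:01	0.017	0.052
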