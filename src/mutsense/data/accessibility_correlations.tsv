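protein	prof	netsurfp	spider3
Aminoglycoside kinase	0.66	0.75	0.69
BRCA1 RING domain	0.45	0.62	0.66
CcdB	0.71	0.75	0.74
Gal4 (DBD)	0.73	0.77	0.66
GB1 (IgG-binding domain)	0.67	0.52	0.64
Hsp90 (ATPase domain)	0.56	0.64	0.59
NUDT15	0.55	0.63	0.62
Pab1 (RRM domain)	0.75	0.81	0.77
PSD (pdz3 domain)	0.74	0.81	0.61
TEM1 beta-lactamase	0.74	0.81	0.79
Ubiquitin	0.74	0.84	0.73
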