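dataset	sensitivity	specificity	accuracy	mcc
Aminoglycoside kinase	72.7	87.7	87.1	0.34
BRCA1 RING domain-BARD1 binding	45.5	91.4	85.2	0.37
BRCA1 RING domain-E3 ligase activity	50	92.3	86.6	0.42
CcdB	75	98.9	96.9	0.79
Gal4 (DBD)	46.6	86.1	75.9	0.34
GB1 (IgG-binding domain)	85.7	91.5	90.7	0.66
Hsp90 (ATPase domain)	93.3	92	92.1	0.63
NUDT15	50	91.2	85.4	0.41
Pab1 (RRM domain)	62.5	87.9	85.1	0.41
PSD (pdz3 domain)	75	90.6	89.2	0.53
TEM1 beta-lactamase	66.6	85.8	85.2	0.26
Ubiquitin	70	96.4	92.3	0.69
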