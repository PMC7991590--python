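dataset	sensitivity	specificity	accuracy	mcc
Aminoglycoside kinase	66.6	90.8	85.6	0.57
BRCA1 RING domain-BARD1 binding	38.5	88.2	80.2	0.27
BRCA1 RING domain-E3 ligase activity	38.5	80.6	73.3	0.12
CcdB	68.4	96.1	90.6	0.69
Gal4 (DBD)	50	78.6	77.6	0.13
GB1 (IgG-binding domain)	70	90.9	87	0.58
Hsp90 (ATPase domain)	18.8	84.7	73.5	0.06
NUDT15	69.7	88	84.2	0.55
Pab1 (RRM domain)	80	89.8	87.8	0.65
PSD (pdz3 domain)	55	90.5	81.9	0.48
TEM1 beta-lactamase	59.8	91.5	80.9	0.55
Ubiquitin	45.5	83.3	76.9	0.26
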