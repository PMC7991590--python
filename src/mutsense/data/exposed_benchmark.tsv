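dataset	sensitivity	specificity	accuracy	mcc
Aminoglycoside kinase	94.9	22.1	76.1	0.25
BRCA1 RING domain-BARD1 binding	94.7	25	74.1	0.29
BRCA1 RING domain-E3 ligase activity	92.3	34.8	74.7	0.34
CcdB	97.1	29.6	78.1	0.39
Gal4 (DBD)	92.3	41.2	77.5	0.41
GB1 (IgG-binding domain)	89.2	35.3	72.2	0.29
Hsp90 (ATPase domain)	92.3	36.2	80	0.34
NUDT15	90.3	23.6	67	0.27
Pab1 (RRM domain)	94.2	50	81.1	0.52
PSD (pdz3 domain)	92.7	35.7	73.5	0.36
TEM1 beta-lactamase	92.0	31	68.8	0.3
Ubiquitin	97.8	40	80	0.5
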