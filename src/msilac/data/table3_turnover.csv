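protein_name,control_48h_pct,ot_12h_pct,ot_48h_pct
Endoplasmin,71,,42
Heat shock cognate 71 kDa protein,65,,52
Ribonuclease inhibitor,59,,36
Annexin A1,55,,37
Glyceraldehyde-3-phosphate dehydrogenase,61,,70
Heterogeneous nuclear ribonucleoprotein F,63,,78
Heterogeneous nuclear ribonucleoproteins A2/B1,67,,45
Peroxiredoxin-4,65,,73
Peroxiredoxin-6,70,,52
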