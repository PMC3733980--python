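spot_id,protein_name,accession,ratio_0uM,ratio_5uM,ratio_50uM,ratio_500uM
1,Endoplasmin,P14625,1.00,0.27,0.33,0.20
2,Heat shock cognate 71 kDa protein,P11142,1.00,0.41,0.25,0.19
3,Heat shock cognate 71 kDa protein,P11142,1.00,3.13,2.58,2.79
4,Elongation factor 2,P13639,1.00,0.13,0.09,0.21
5,Heat shock protein HSP 90-beta,P08238,1.00,0.26,0.18,0.14
6,Protein disulfide-isomerase,P07237,1.00,0.07,0.22,0.09
7,Ribonuclease inhibitor,P13489,1.00,0.17,0.24,0.19
8,Heterogeneous nuclear ribonucleoproteins A2/B1,P22626,1.00,7.51,11.45,10.96
9,Guanine nucleotide-binding protein subunit beta-2-like 1,P63244,1.00,0.65,0.43,0.38
10,Eukaryotic translation initiation factor 4H,Q15056,1.00,0.32,0.15,0.27
11,Eukaryotic translation initiation factor 6,P56537,1.00,0.40,0.24,0.17
12,Glutathione S-transferase P,P09211,1.00,0.61,0.57,0.26
13,Phosphatidylethanolamine-binding protein 1,P30086,1.00,0.63,0.29,0.30
14,GTP-binding nuclear protein Ran,P62826,1.00,0.37,0.42,0.15
15,Myosin light polypeptide 6,P60660,1.00,0.34,0.49,0.08
16,Transketolase,P51854,1.00,4.17,3.30,1.85
17,Alpha-enolase,Q6GMP2,1.00,0.89,2.13,2.29
18,14-3-3 protein beta/alpha,P31946,1.00,0.76,0.50,0.55
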