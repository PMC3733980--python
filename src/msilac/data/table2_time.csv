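spot_id,protein_name,accession,printed_cluster,total_0h,total_24h,total_48h,phospho_0h,phospho_24h,phospho_48h
1,Nuclear autoantigenic sperm protein,P49321,e,1.00,0.37,1.35,1.00,0.09,0.05
2,Endoplasmin,P14625,f,1.00,1.17,0.26,,,
3,Neutral alpha-glucosidase AB,Q14697,e,1.00,0.41,0.89,,,
4,Heat shock cognate 71 kDa protein,P11142,d,1.00,0.62,0.45,1.00,0.13,0.08
5,Transketolase,P29401,f,1.00,3.23,0.77,,,
6,Stress-induced-phosphoprotein 1,P31948,d,1.00,0.61,0.28,1.00,1.17,0.19
7,Protein disulfide-isomerase A3,P30101,d,1.00,0.30,0.06,,,
8,T-complex protein 1 subunit alpha,P17987,d,1.00,0.39,0.21,,,
9,Coronin-1A,P31146,e,1.00,0.45,0.74,,,
10,Heterogeneous nuclear ribonucleoprotein H,P31943,d,1.00,0.88,0.49,,,
11,Protein disulfide-isomerase,P07237,e,1.00,0.37,0.84,,,
12,Ribonuclease inhibitor,P13489,d,1.00,0.91,0.23,,,
13,Calreticulin,P27797,f,1.00,3.58,0.95,,,
14,Alpha-enolase,P06733,f,1.00,2.37,0.82,1.00,0.24,0.07
15,40S ribosomal protein SA,Q86VC0,f,1.00,1.35,2.00,,,
16,Heterogeneous nuclear ribonucleoprotein F,P52597,e,1.00,0.31,0.73,,,
17,F-actin-capping protein subunit alpha-1,P52907,e,1.00,0.49,0.81,,,
18,Eukaryotic translation initiation factor 3 subunit I,O75821,e,1.00,0.29,0.72,1.00,0.73,0.29
19,F-actin-capping protein subunit alpha-2,P47755,e,1.00,0.43,0.87,1.00,0.20,0.03
20,Annexin A1,P04083,d,1.00,0.87,0.48,,,
21,Glyceraldehyde-3-phosphate dehydrogenase,P04406,e,1.00,0.39,1.25,,,
22,Glyceraldehyde-3-phosphate dehydrogenase,P04406,e,1.00,0.41,1.32,,,
23,Heterogeneous nuclear ribonucleoprotein A1,P09651,e,1.00,0.17,1.39,,,
24,Heterogeneous nuclear ribonucleoproteins A2/B1,P22626,e,1.00,0.06,0.33,,,
25,Aldo-keto reductase family 1 member C2,P52895,e,1.00,0.48,4.02,,,
26,Serine/threonine-protein kinase 13,Q9BYE2,d,1.00,0.11,0.07,,,
27,Annexin A5,P08758,d,1.00,0.43,0.36,,,
28,14-3-3 protein epsilon,Q9Y275,d,1.00,0.34,0.12,1.00,0.36,0.15
29,14-3-3 protein beta/alpha,P31946,d,1.00,0.39,0.22,1.00,0.31,0.74
30,14-3-3 protein zeta/delta,P63104,d,1.00,0.42,0.28,1.00,0.87,0.14
31,Eukaryotic translation initiation factor 6,P56537,e,1.00,0.39,0.47,1.00,0.76,0.41
32,Tumor necrosis factor ligand superfamily member 13B,P62258,f,1.00,2.13,0.29,1.00,0.33,0.17
33,Septin-14,Q6ZU15,e,1.00,0.04,0.78,,,
34,Peroxiredoxin-4,Q13162,e,1.00,0.20,0.53,,,
35,Phosphoglycerate mutase 1,P18669,e,1.00,0.08,2.59,,,
36,Guanine nucleotide-binding protein subunit beta-2-like 1,P63244,e,1.00,0.49,0.91,,,
37,Heat shock protein beta-1,P04792,d,1.00,0.43,0.28,,,
38,Peroxiredoxin-6,P30041,d,1.00,0.89,0.37,,,
39,Glutathione S-transferase P,P09211,d,1.00,0.77,0.42,1.00,0.26,0.04
40,Stathmin,P16949,e,1.00,0.35,0.46,,,
41,Nucleoside diphosphate kinase A,P15531,d,1.00,0.97,0.09,,,
42,Peroxiredoxin-2,P32119,e,1.00,0.37,0.49,,,
43,Myosin light polypeptide 6,P60660,d,1.00,0.88,0.23,,,
44,Putative uncharacterized protein NCRNA00188,Q8N1F1,f,1.00,1.15,0.50,,,
45,Protein S100-A8,P05109,e,1.00,0.29,0.73,,,
46,Peptidyl-prolyl cis-trans isomerase A,P62937,e,1.00,0.07,0.19,,,
47,Loss of heterozygosity 12 chromosomal region 1 protein,Q969J3,,,,,1.00,0.13,0.02
48,Eukaryotic translation initiation factor 5A-1,P63241,,,,,1.00,0.14,0.05
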