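taxon,abundance_A,indval_A,abundance_B,indval_B,abundance_C,indval_C
Acartia pacifica,18.83,58.83,7.8,23.92,0.04,0.04
Acrocalanus monachus,1.47,3.86,0.63,1.8,4.25,50.22
Calanopia elliptica,8.43,67.25,1.71,11.91,0.31,0.73
Candacia aethiopica,0.17,1.29,0.35,5.88,1.66,66.60
Candacia (copepodites),,,,,5.15,75.00
Canthocalanus pauper,60.86,65.25,23.44,22.85,8.96,9.61
Centropages calaninus,,,0.25,4.89,1.13,61.56
Centropages furcatus,0.27,14.72,1.28,52.4,,
Copilia mirabilis,0.1,1.49,0.17,2.74,3.09,92.01
Corycaeus agilis,4.03,2.1,10.26,23.38,17.63,55.22
Corycaeus speciosus,7.62,55.44,1.52,12.07,2.31,15.15
Euchaeta concinna,12.29,61.12,4.36,23.68,0.1,0.15
Euchaeta (copepodites),31.1,20.96,62.2,51.45,5.61,1.42
Farranula concinna,1.31,0.62,0.69,0.71,33.32,94.36
Farranula gibbula,8.34,10.67,17.4,30.38,26.33,50.58
Macrosetella gracilis,15.41,57.31,7.08,26.35,4.39,16.34
Oncaea clevei,8.74,18.86,21.31,55.19,8.56,11.09
Paracalanus aculeatus,184.75,44.96,217.13,52.83,9.09,1.38
Paracalanus parvus,42.82,53.58,23.94,19.06,13.16,8.23
Paracandacia truncata,0.17,8.03,1.18,69.47,0.04,1.53
Temora discaudata,10.66,61.82,4.5,26.08,2.09,7.56
Temora turbinata,78.28,69.06,16.07,15.47,0.1,0.01
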