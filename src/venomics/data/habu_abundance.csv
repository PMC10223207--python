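taxon,SVMP,SVSP,PLA2,CRISP,Disintegrin,BPP/CNP,CTL,LAAO,VEGF,NGF,PDE,5NT,PLB,QC,Others,Unknown
P. cornutus,16.17,11.69,37.68,3.79,3.51,6.57,14.36,4.27,0.51,0.05,0.99,0.08,0.32,,,0.01
P. jerdonii,21.76,21.43,22.10,2.19,15.25,6.93,1.59,2.45,5.33,0.19,0.19,0.39,0.14,0.04,,0.02
P. mangshanensis (subadult),22.06,10.90,1.23,8.73,,3.26,51.47,0.17,0.39,0.22,1.06,,0.10,,,0.41
P. mucrosquamatus,43.07,12.30,24.51,0.88,1.21,7.79,4.78,3.06,0.89,0.01,0.80,0.70,,,,
P. mucrosquamatus (Taiwan),43.40,10.40,23.50,0.80,0.80,3.60,3.90,2.00,,,,,,,3.30,
P. sieversorum,32.47,21.33,16.14,1.64,5.79,8.02,8.97,3.54,1.14,,0.24,0.12,0.08,0.23,,0.29
P. xiangchengensis,49.34,14.58,14.21,1.92,1.32,11.04,4.20,1.66,1.11,,0.33,0.15,,0.004,,0.13
P. elegans,39.40,9.50,22.50,1.80,,0.10,2.90,9.80,1.80,0.50,4.10,2.80,2.20,1.40,1.00,0.30
P. flavoviridis,31.34,1.44,55.14,1.83,,,2.78,0.71,,,0.07,0.02,,,6.39,0.27
P. kelomohy,40.85,29.93,15.49,1.41,0.35,,,3.87,0.70,1.76,,,,,5.63,
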