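taxon,ld50_ug_per_g,ci_low,ci_high
P. cornutus,0.61,0.46,0.81
P. jerdonii,1.91,1.73,2.11
P. mangshanensis (subadult),1.23,0.98,1.54
P. mucrosquamatus,3.82,3.50,4.17
P. mucrosquamatus (Taiwan),2.17,,
P. sieversorum,1.23,1.07,1.41
P. xiangchengensis,1.79,1.51,2.11
P. elegans,4.85,,
P. flavoviridis,2.60,,
P. kelomohy,0.67,0.58,0.78
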