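taxon,P. cornutus,P. jerdonii,P. mucrosquamatus,P. sieversorum,P. xiangchengensis
P. cornutus,,14.4,15.8,18.9,9.6
P. jerdonii,14.4,,15.2,14.3,23.7
P. mucrosquamatus,15.8,15.2,,39.2,18.0
P. sieversorum,18.9,14.3,39.2,,7.6
P. xiangchengensis,9.6,23.7,18.0,7.6,
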