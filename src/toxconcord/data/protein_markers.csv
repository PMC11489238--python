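marker,cellular_function
p-elF4B,Translation
p-RNA pol II,Transcription
Ubiquitin k48,Protein degradation
p-Histone H3,Cell division
HSP70,Oxidative/heat stress
cleaved PARP,Apoptosis
total LC3B,Autophagy
HIF 1-alpha,Hypoxia
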