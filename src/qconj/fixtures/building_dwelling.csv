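exemplar,concept_a,concept_b,mu_a,mu_b,mu_ab
cave,Building,Dwelling,0.28,0.85,0.28
synagogue,Building,Dwelling,0.93,0.49,0.45
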