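exemplar,concept_a,concept_b,mu_a,mu_b,mu_ab
sailboat,Machine,Vehicle,0.56,0.8,0.42
skateboard,Machine,Vehicle,0.28,0.84,0.34
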