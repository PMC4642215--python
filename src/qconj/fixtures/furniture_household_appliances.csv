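exemplar,concept_a,concept_b,mu_a,mu_b,mu_ab
filing cabinet,Furniture,Household Appliances,0.97,0.31,0.53
heated waterbed,Furniture,Household Appliances,1,0.49,0.78
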