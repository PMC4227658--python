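collagen_density_mg_ml,elastic_modulus_pa
1.0,3.03
2.0,44.50
3.0,97.38
4.0,123.5
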