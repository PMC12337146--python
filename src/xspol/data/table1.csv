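quantity,value
alpha_tilde_calc,1.7367
alpha_bar_calc,2.0035
alpha_tilde_exp,1.7871
alpha_bar_exp,2.0612
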