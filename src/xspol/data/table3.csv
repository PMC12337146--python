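sequence,cc_pvdz,aug_cc_pvdz,ratio
CT,58.0,68.4,1.1799
TAT,93.4,109.4,1.1703
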