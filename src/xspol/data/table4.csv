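sequence,alpha_bar,molar_mass
CT,68.4,530.4
CTA,108.1,842.6
CTATC,181.5,1434.0
CTATCT,219.1,1737.1
CTATCTCA,295.2,2337.5
CTATCTCAG,335.9,2665.7
CTATCTCAGTC,409.0,3257.1
TAT,109.4,857.6
TATGA,190.2,1498.0
TATGAA,229.2,1810.2
TATGAATT,305.2,2416.6
TATGAATTC,341.0,2704.8
TATGAATTCAAT,458.0,3632.3
TATGAATTCAATCC,529.8,4208.7
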