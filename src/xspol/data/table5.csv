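sequence,alpha_computed,alpha_experimental,misprint
CT,35.5,36.1,0
CTA,58.3,57.5,0
CTATC,99.0,98.3,0
CTATCT,119.6,119.2,0
CTATCTCA,161.9,160.7,0
CTATCTCAG,185.4,183.4,0
CTATCTCAGTC,225.7,224.3,0
TAT,58.6,58.6,0
TATGA,105.0,102.8,0
TATGAA,127.1,124.6,0
TATGAATT,169.3,166.4,0
TATGAATTC,188.9,186.2,0
TATGAATTCAAT,254.0,2450.6,1
TATGAATTCAATCC,293.4,290.3,0
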