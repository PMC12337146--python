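element,radius
H,1.4430
He,1.1810
Li,1.2255
Be,1.3725
B,2.0415
C,1.9255
N,1.8300
O,1.7500
F,1.6820
Ne,1.6215
Na,1.4915
Mg,1.5105
Al,2.2495
Si,2.1475
P,2.0735
S,2.0175
Cl,1.9735
K,1.9060
Ca,1.6995
Fe,1.4560
Zn,1.2915
Br,1.8655
I,2.2500
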