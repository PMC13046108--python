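element,mass_fraction
O,0.62
C,0.20
H,0.10
N,0.03
Na,0.014
K,0.014
P,0.016
S,0.004
Ca,0.0007
Zn,0.00013
Fe,0.00019
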