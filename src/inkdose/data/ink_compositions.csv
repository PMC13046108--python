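color,element,wet_ppm,below_loq
brown,Al,105,0
brown,V,11.0,0
brown,Cr,147,0
brown,Fe,88400,0
brown,Co,6.44,0
brown,Ni,9.59,0
brown,Cu,260,0
brown,Cd,0.35,0
brown,Ba,19.3,0
brown,Hg,0.15,0
brown,Pb,8.13,0
orange,Al,1830,0
orange,V,19.3,0
orange,Cr,2.99,0
orange,Fe,0.89,0
orange,Co,32.4,0
orange,Ni,13.0,0
orange,Cu,0,1
orange,Cd,0.14,0
orange,Ba,0.29,0
orange,Hg,0.32,0
orange,Pb,1.51,0
black,Al,9.36,0
black,V,0.098,0
black,Cr,1.55,0
black,Fe,6.42,0
black,Co,0.011,0
black,Ni,0.070,0
black,Cu,5.02,0
black,Cd,0.013,0
black,Ba,0.17,0
black,Hg,0.011,0
black,Pb,0.057,0
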