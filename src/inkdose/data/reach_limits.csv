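element,limit_ppm
Cr,0.5
Co,0.5
Ni,5
Cu,250
Cd,0.5
Ba,500
Hg,0.5
Pb,0.7
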