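color,compound,density_g_cm3
brown,Fe2O3,5.3
orange,Al(OH)3,2.4
black,carbon-black,1.8
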