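# Printed tattoo-dermis mixture densities (g/cm^3) at each pigment loading,
# as published; used to diff regenerated values against the printed table.
color,loading_vol_percent,printed_density
brown,0,1.1
brown,5,1.3
brown,10,1.5
brown,25,2.1
brown,50,3.2
brown,75,4.2
brown,100,5.3
orange,0,1.1
orange,5,1.2
orange,10,1.2
orange,25,1.4
orange,50,1.8
orange,75,2.1
orange,100,2.4
black,0,1.1
black,5,1.1
black,10,1.2
black,25,1.3
black,50,1.5
black,75,1.6
black,100,1.8
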