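# Printed REACH compliance column: which inks exceed each limited element.
# "-" means no ink exceeds (within limits everywhere).
element,exceeds_in
Cr,"brown,orange,black"
Co,"brown,orange"
Ni,"brown,orange"
Cu,"brown"
Cd,"-"
Ba,"-"
Hg,"-"
Pb,"brown,orange"
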