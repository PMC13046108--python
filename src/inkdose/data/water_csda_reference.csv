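# Reference CSDA ranges for electrons in liquid water (g/cm^2), transcribed
# once from a standard published stopping-power/range compilation. Independent
# oracle for the condensed-history electron transport.
energy_mev,csda_range_g_cm2
0.1,0.0143
0.5,0.1766
1.0,0.4367
2.0,0.9785
6.0,3.052
10.0,4.975
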