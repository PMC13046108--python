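# Reference mass attenuation coefficients for liquid water (cm^2/g),
# transcribed once from standard published photon cross-section compilations.
# "total" includes coherent (Rayleigh) scattering; "photoelectric" is the
# photoelectric component alone. Used only as an independent oracle and as
# the anchor for the pair-production scaling model.
energy_mev,total,photoelectric
0.1,0.1707,0.00276
0.5,0.0969,0.0
1.0,0.0707,0.0
2.0,0.0494,0.0
5.0,0.0303,0.0
6.0,0.0277,0.0
8.0,0.0243,0.0
10.0,0.0222,0.0
15.0,0.0191,0.0
20.0,0.0181,0.0
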