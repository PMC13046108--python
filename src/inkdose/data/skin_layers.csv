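name,thickness_um,density_g_cm3
upper_SC,8.5,1.3
middle_SC,12.8,1.2
lower_SC,12.8,1.1
stratum_granulosum,8,1.1
stratum_spinosum,50,1.1
stratum_basale,8,1.1
papillary_dermis,400,1.1
reticular_dermis,1900,1.1
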