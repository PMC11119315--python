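wavelength_nm,chromophore,epsilon_per_mM_mm
760,HbO,0.14866
760,HbR,0.38437
850,HbO,0.25264
850,HbR,0.17986
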