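nuclide,half_life_h,e_max_MeV
Au-198,64.8,0.96
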