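tumor_radius_cm,activity_mCi,dose_Gy,provenance
0.25,187.9,72,abstract
0.5,300,118,abstract
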