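tumor_radius_cm,activity_mCi,dose_Gy,provenance
0.25,185.6,71.5,results
0.5,212.4,89.9,results
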