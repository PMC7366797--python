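energy_keV,geometry,coefficient_mSv_per_mGy
662,AP,1.21
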