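model_code,energy_keV,geometry,response_per_hp10
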