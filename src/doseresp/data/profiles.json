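{
  "NPP": {
    "energy_fractions": {"band_0_100": 0.0, "band_100_300": 0.10, "band_300_3000": 0.90},
    "geometry_fractions": {"AP": 0.5, "ISO": 0.5, "ROT": 0.0}
  },
  "MA": {
    "energy_fractions": {"band_0_100": 0.0, "band_100_300": 0.20, "band_300_3000": 0.80},
    "geometry_fractions": {"AP": 0.5, "ISO": 0.5, "ROT": 0.0}
  }
}
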