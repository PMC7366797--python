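{
  "old_FB": ["FR-1", "US-2", "UK-2", "UK-5"],
  "multi_element_FB": ["UK-9", "US-8", "FR-6"],
  "TLD": ["US-22"]
}
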