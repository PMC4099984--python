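{
  "_comment": "Physical half-lives (hours) of the three thyroid agents.",
  "I-131": {"half_life_h": 192.605},
  "I-123": {"half_life_h": 13.2235},
  "Tc-99m": {"half_life_h": 6.0072}
}
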