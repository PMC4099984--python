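# I-123 (electron capture, T1/2 13.2235 h)
# Nominal line list transcribed from standard decay-data compilations (ENSDF-derived tabulations); energies MeV, yields per decay. Editable; checksums guard against silent edits.
particle,origin,energy_MeV,yield_per_decay,tag,z_daughter,sign
photon,gamma,0.15897,0.833,g159,,
photon,gamma,0.34635,0.00126,g346,,
photon,gamma,0.44002,0.00428,g440,,
photon,gamma,0.50533,0.00316,g505,,
photon,gamma,0.52896,0.0139,g529,,
photon,gamma,0.53854,0.00382,g539,,
photon,gamma,0.62457,0.000834,g625,,
photon,gamma,0.68795,0.00024,g688,,
photon,xray,0.027202,0.246,Ka2,,
photon,xray,0.027472,0.459,Ka1,,
photon,xray,0.03098,0.1005,Kb1,,
photon,xray,0.0317,0.0226,Kb2,,
photon,xray,0.0041,0.0088,L,,
electron,conversion,0.12719,0.136,K,,
electron,conversion,0.15433,0.0178,L,,
electron,conversion,0.15828,0.00379,M,,
electron,conversion,0.49717,0.00032,K,,
electron,auger,0.0227,0.115,K,,
electron,auger,0.00319,0.94,L,,
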