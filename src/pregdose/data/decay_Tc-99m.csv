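# Tc-99m (isomeric transition, T1/2 6.0072 h)
# Nominal line list transcribed from standard decay-data compilations (ENSDF-derived tabulations); energies MeV, yields per decay. Editable; checksums guard against silent edits.
particle,origin,energy_MeV,yield_per_decay,tag,z_daughter,sign
photon,gamma,0.140511,0.885,g141,,
photon,xray,0.018251,0.0213,Ka2,,
photon,xray,0.018367,0.0406,Ka1,,
photon,xray,0.020619,0.0122,Kb,,
photon,xray,0.0024,0.0075,L,,
electron,conversion,0.119467,0.088,K,,
electron,conversion,0.1375,0.0107,L,,
electron,conversion,0.14,0.00206,M,,
electron,conversion,0.00174,0.991,M2,,
electron,auger,0.0153,0.0203,K,,
electron,auger,0.00178,0.98,L,,
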