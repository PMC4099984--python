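# I-131 (beta-minus, T1/2 8.0252 d)
# Nominal line list transcribed from standard decay-data compilations (ENSDF-derived tabulations); energies MeV, yields per decay. Editable; checksums guard against silent edits.
particle,origin,energy_MeV,yield_per_decay,tag,z_daughter,sign
photon,gamma,0.080185,0.0262,g80,,
photon,gamma,0.284305,0.0612,g284,,
photon,gamma,0.32578,0.00274,g326,,
photon,gamma,0.364489,0.815,g364,,
photon,gamma,0.502991,0.0036,g503,,
photon,gamma,0.636989,0.0716,g637,,
photon,gamma,0.642719,0.00217,g643,,
photon,gamma,0.722911,0.0177,g723,,
photon,xray,0.029461,0.0139,Ka2,,
photon,xray,0.029782,0.0257,Ka1,,
photon,xray,0.033624,0.00884,Kb,,
electron,conversion,0.045626,0.0355,K,,
electron,conversion,0.329928,0.0155,K,,
electron,conversion,0.249744,0.00251,K,,
electron,conversion,0.07473,0.00464,L,,
electron,conversion,0.359336,0.00246,L,,
electron,conversion,0.079193,0.00109,M,,
electron,conversion,0.363786,0.00049,M,,
electron,auger,0.0246,0.0055,K,,
electron,auger,0.00334,0.051,L,,
beta,beta,0.2479,0.0208,b1,54,minus
beta,beta,0.30387,0.00618,b2,54,minus
beta,beta,0.33381,0.0723,b3,54,minus
beta,beta,0.60631,0.896,b4,54,minus
beta,beta,0.6297,0.00048,b5,54,minus
beta,beta,0.8069,0.004,b6,54,minus
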