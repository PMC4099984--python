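{
 "_comment": "Transfer-rate constants (per day) for the iodide-in-pregnancy compartmental model. The published pregnancy biokinetic model this structure follows does not print its rate constants, so these defaults are package choices: renal clearance, salivary/gastric secretion with gut reabsorption, thyroid hormone turnover and transplacental exchange are set to physiologically conventional values that reproduce the qualitative uptake-level trends (maternal thyroid rising, fetal thyroid / stomach falling, liver rising). blood_to_thyroid is not listed: it is solved at run time so the no-decay asymptotic thyroid uptake equals the requested maximum uptake F. Edit freely; the model builder reads this file.",
 "blood_to_kidneys": 3.0,
 "blood_to_salivary": 1.0,
 "blood_to_stomach": 6.0,
 "blood_to_ecf": 8.0,
 "ecf_to_blood": 40.0,
 "blood_to_fetus": 0.105,
 "kidneys_to_urine": 300.0,
 "salivary_to_stomach": 12.0,
 "stomach_to_si": 30.0,
 "si_to_blood": 25.0,
 "thyroid_to_organic": 0.0087,
 "organic_to_liver": 4.0,
 "liver_to_organic": 7.0,
 "organic_to_blood": 0.1,
 "organic_to_feces": 0.012,
 "fetus_to_fetal_thyroid": 2.0,
 "fetus_to_blood": 1.0,
 "fetal_thyroid_to_fetus": 0.0087
}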