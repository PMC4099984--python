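# Published organ doses (mGy/MBq) for I-131 sodium iodide in the 9-months pregnant hybrid phantom: seven maximum-thyroid-uptake levels computed with the pregnancy biokinetics, plus columns using the two reference cumulated-activity sets (russell, icrp53) and the stylized-model fetal doses (stylized).
target,u05,u15,u25,u35,u45,u55,u95,russell,icrp53,stylized
Active red marrow,7.55E-02,1.48E-01,2.22E-01,3.01E-01,3.64E-01,4.42E-01,7.68E-01,2.17E-01,2.17E-01,
Colon,6.38E-02,6.46E-02,6.55E-02,6.64E-02,6.71E-02,6.81E-02,7.25E-02,6.51E-02,6.59E-02,
Lungs,9.35E-02,1.86E-01,2.79E-01,3.79E-01,4.60E-01,5.59E-01,9.72E-01,2.73E-01,2.77E-01,
Stomach wall,7.12E-01,6.55E-01,5.97E-01,5.36E-01,4.86E-01,4.25E-01,1.70E-01,6.14E-01,7.48E-01,
Breasts,4.69E-02,8.63E-02,1.26E-01,1.69E-01,2.03E-01,2.46E-01,4.22E-01,1.24E-01,1.25E-01,
Ovaries,6.46E-02,6.04E-02,5.63E-02,5.20E-02,4.85E-02,4.44E-02,3.29E-02,6.99E-02,6.14E-02,
Urinary bladder wall,1.52E-01,1.39E-01,1.26E-01,1.12E-01,1.01E-01,8.77E-02,5.25E-02,1.72E-01,1.32E-01,
Esophagus,4.30E-01,1.23E+00,2.05E+00,2.92E+00,3.62E+00,4.49E+00,8.09E+00,2.00E+00,1.99E+00,
Liver,1.20E-01,1.64E-01,2.09E-01,2.57E-01,2.96E-01,3.44E-01,5.43E-01,1.81E-01,7.95E-02,
Thyroid,8.17E+01,2.48E+02,4.17E+02,5.97E+02,7.42E+02,9.20E+02,1.66E+03,4.06E+02,4.04E+02,
Endosteal region,4.36E-02,7.63E-02,1.10E-01,1.45E-01,1.73E-01,2.09E-01,3.55E-01,1.07E-01,1.09E-01,
Salivary gland,9.72E-01,1.04E+00,1.10E+00,1.17E+00,1.23E+00,1.30E+00,1.58E+00,3.77E-01,3.76E-01,
Adrenal,6.94E-02,7.89E-02,8.86E-02,9.90E-02,1.07E-01,1.18E-01,1.61E-01,8.68E-02,8.17E-02,
Kidney,9.59E-02,9.86E-02,1.01E-01,1.04E-01,1.07E-01,1.10E-01,1.22E-01,6.45E-02,1.10E-01,
Pancreas,9.61E-02,9.77E-02,9.93E-02,1.01E-01,1.02E-01,1.04E-01,1.11E-01,1.02E-01,1.09E-01,
SI-wall,3.48E-01,3.18E-01,2.88E-01,2.57E-01,2.31E-01,1.99E-01,6.82E-02,2.92E-01,3.21E-01,
Spleen,8.04E-02,8.67E-02,9.31E-02,9.99E-02,1.05E-01,1.12E-01,1.40E-01,9.21E-02,1.02E-01,
Thymus,3.62E-01,1.05E+00,1.74E+00,2.49E+00,3.08E+00,3.82E+00,6.89E+00,1.70E+00,1.70E+00,
Uterus,7.66E-02,7.32E-02,6.98E-02,6.62E-02,6.34E-02,5.98E-02,4.65E-02,7.27E-02,7.34E-02,
Remainder tissues,1.32E-01,2.41E-01,3.51E-01,4.69E-01,5.63E-01,6.80E-01,1.17E+00,3.41E-01,3.47E-01,
Placenta,5.79E-02,5.50E-02,5.22E-02,4.91E-02,4.67E-02,4.37E-02,3.31E-02,6.58E-02,6.53E-02,
Fetus,3.08E-01,2.81E-01,2.55E-01,2.26E-01,2.03E-01,1.75E-01,5.85E-02,2.41E-01,2.40E-01,2.70E-01
"Fetus, brain",1.11E-01,1.02E-01,9.28E-02,8.28E-02,7.47E-02,6.48E-02,2.49E-02,2.43E-01,2.41E-01,
"Fetus, skeleton",1.35E-01,1.27E-01,1.19E-01,1.10E-01,1.03E-01,9.45E-02,5.88E-02,2.32E-01,2.32E-01,
"Fetus, eyes",1.08E-01,9.95E-02,9.12E-02,8.23E-02,7.51E-02,6.63E-02,3.01E-02,2.48E-01,2.48E-01,
"Fetus, spinal cord",3.65E-01,3.32E-01,2.99E-01,2.64E-01,2.36E-01,2.01E-01,5.68E-02,2.46E-01,2.48E-01,
"Fetus, thyroid",4.35E+02,3.92E+02,3.49E+02,3.03E+02,2.65E+02,2.20E+02,2.90E+01,1.12E-01,1.13E-01,2.70E+02
"Fetus, lungs",2.07E-01,1.91E-01,1.74E-01,1.56E-01,1.41E-01,1.23E-01,4.92E-02,3.50E-01,3.52E-01,
"Fetus, thymus",1.25E+00,1.13E+00,1.01E+00,8.79E-01,7.75E-01,6.46E-01,1.12E-01,2.50E-01,2.51E-01,
"Fetus, heart",2.18E-01,2.01E-01,1.83E-01,1.64E-01,1.49E-01,1.30E-01,5.16E-02,2.59E-01,2.60E-01,
"Fetus, liver",9.32E-02,8.83E-02,8.33E-02,7.80E-02,7.38E-02,6.85E-02,4.68E-02,2.52E-01,2.53E-01,
"Fetus, kidneys",7.67E-02,7.56E-02,7.44E-02,7.32E-02,7.22E-02,7.10E-02,6.61E-02,2.55E-01,2.56E-01,
"Fetus, adrenals",9.37E-02,8.96E-02,8.55E-02,8.11E-02,7.75E-02,7.31E-02,5.49E-02,2.58E-01,2.60E-01,
"Fetus, spleen",1.08E-01,1.03E-01,9.87E-02,9.39E-02,9.00E-02,8.52E-02,6.54E-02,2.66E-01,2.70E-01,
"Fetus, SI wall",8.51E-02,8.41E-02,8.31E-02,8.20E-02,8.12E-02,8.01E-02,7.59E-02,2.63E-01,2.63E-01,
"Fetus, LI wall",6.58E-02,6.67E-02,6.77E-02,6.88E-02,6.96E-02,7.06E-02,7.51E-02,2.54E-01,2.54E-01,
"Fetus, bladder wall",6.46E-02,6.48E-02,6.51E-02,6.53E-02,6.55E-02,6.58E-02,6.70E-02,2.55E-01,2.54E-01,
"Fetus, stomach wall",1.15E-01,1.09E-01,1.03E-01,9.68E-02,9.17E-02,8.53E-02,5.90E-02,2.63E-01,2.65E-01,
"Fetus, gall bladder wall",7.52E-02,7.23E-02,6.94E-02,6.63E-02,6.39E-02,6.08E-02,4.82E-02,2.52E-01,2.52E-01,
"Fetus, pancreas",9.86E-02,9.51E-02,9.16E-02,8.78E-02,8.48E-02,8.10E-02,6.55E-02,2.65E-01,2.67E-01,
"Fetus, soft tissue",1.56E-01,1.45E-01,1.33E-01,1.21E-01,1.11E-01,9.92E-02,4.93E-02,2.40E-01,2.39E-01,
"Fetus, skin",7.77E-02,7.41E-02,7.04E-02,6.65E-02,6.34E-02,5.95E-02,4.41E-02,2.07E-01,2.07E-01,
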