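# Active (red) marrow mass fractions by skeletal site for the adult female,
# following the reference-phantom convention of weighting skeletal-site doses
# by their active-marrow content. Values are a configurable table; fractions
# sum to 1.
site,fraction
cranium,0.076
mandible,0.008
scapulae,0.028
clavicles,0.008
sternum,0.031
ribs,0.161
cervical_spine,0.039
thoracic_spine,0.161
lumbar_spine,0.123
sacrum,0.099
os_coxae,0.175
femora,0.067
humeri,0.023
other,0.001
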