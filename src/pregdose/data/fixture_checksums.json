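{
 "decay_I-131.csv": "657bfb8e24e1bd23e8d57c262b01b4dcf5289411e7a29c027389cab6197086f2",
 "decay_I-123.csv": "10a80cc26c097b1bdfea56ab9580d3d49e001ae7215fffbc5c9fbe217558ca08",
 "decay_Tc-99m.csv": "5dfae1c80c84d296b2f27bd8d6cd6da8d7efa88a6a0bdb665083a309be91a476"
}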