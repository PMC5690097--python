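{
 "H": 0.99212,
 "C": 0.49954,
 "N": 0.49976,
 "O": 0.50002,
 "S": 0.49899,
 "Al": 0.48181,
 "Cu": 0.45636,
 "Gd": 0.40699,
 "W": 0.40252,
 "Air": 0.49919,
 "Water": 0.55509,
 "SoftTissue": 0.55121,
 "CorticalBone": 0.51478
}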