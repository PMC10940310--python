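region,k
head,0.0021
neck,0.0059
head_neck,0.0031
chest,0.014
abdomen,0.015
pelvis,0.015
abdomen_pelvis,0.015
trunk,0.015
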