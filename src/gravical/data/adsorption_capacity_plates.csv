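plate,1,2,3,4,5,6,7,8,9,10,11,12
Plate 1,4.43,4.33,4.32,4.26,4.32,4.34,4.16,4.60,4.29,4.41,4.53,4.29
Plate 2,4.36,4.21,4.61,4.17,4.48,4.39,4.25,4.19,4.15,4.03,4.00,4.36
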