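judge,4,9,15,20,27,32,38,46,52,58,72,76,85,93,99,107
judge1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
judge2,1,1,1,1,1,1,1,1,0,1,1,1,1,1,1,1
judge3,1,1,1,1,0,1,1,1,0,1,0,1,1,1,0,1
judge4,1,1,1,1,0,1,1,1,0,1,0,1,1,1,0,1
judge5,1,1,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge6,1,1,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge7,0,1,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge8,0,1,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge9,0,0,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge10,0,0,0,1,0,1,1,1,0,1,0,1,1,1,0,1
judge11,0,0,0,0,0,1,1,1,0,1,0,1,1,1,0,1
judge12,0,0,0,0,0,1,1,1,0,1,0,1,0,1,0,1
judge13,0,0,0,0,0,1,1,1,0,1,0,1,0,1,0,1
judge14,0,0,0,0,0,0,1,1,0,1,0,1,0,1,0,1
judge15,0,0,0,0,0,0,1,1,0,1,0,1,0,1,0,1
judge16,0,0,0,0,0,0,1,1,0,0,0,1,0,1,0,1
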