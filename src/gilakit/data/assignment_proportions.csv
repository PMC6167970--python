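series,105,133,141,145,152,GR1,68,121,132,140,162,100,112,122,125,150,155
robusta,0.22,0.22,0.26,0.35,0.26,0.39,0.35,0.35,0.30,0.35,0.22,0.22,0.26,0.22,0.35,0.30,0.30
nigra,0.57,0.65,0.70,0.61,0.61,0.65,0.65,0.70,0.70,0.65,0.57,0.65,0.65,0.57,0.78,0.26,0.35
intermedia,0.52,0.57,0.57,0.39,0.57,0.48,0.43,0.52,0.48,0.43,0.57,0.39,0.65,0.43,0.43,0.48,0.39
unclassified,0.17,0.26,0.13,0.22,0.17,0.09,0.13,0.09,0.17,0.22,0.30,0.22,0.13,0.26,0.09,0.13,0.39
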