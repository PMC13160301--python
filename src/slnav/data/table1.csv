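model,rms,registration_accuracy
1,0.41,0.005
2,0.346,0.024
3,0.422,0.025
4,0.387,0.011
5,0.44,0.001
6,0.73,0.001
7,0.4,0.007
8,0.361,0.011
9,0.328,0.007
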