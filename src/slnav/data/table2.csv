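model,neo_grade,entry_offset,exit_offset,angle_offset,failure
1,0,1.197,1.265,0.856,0
2,0,1.192,1.244,1.139,0
3,0,0.725,1.240,0.844,0
4,0,0.923,1.127,0.920,0
5,0,0.736,1.373,0.809,0
6,0,0.742,1.266,0.916,0
7,0,1.012,1.208,1.018,0
8,0,0.832,1.247,0.961,0
9,0,0.822,1.309,0.833,0
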