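expert_id,gamma1,gamma2,gamma3,beta1,beta2,beta3
1,0.65,0.15,0.7,0.65,0.15,0.7
2,0.65,0.16,0.75,0.65,0.16,0.75
3,0.67,0.15,0.78,0.67,0.15,0.78
4,0.7,0.17,0.77,0.7,0.17,0.77
5,0.75,0.14,0.8,0.75,0.14,0.8
6,0.78,0.11,0.81,0.78,0.11,0.81
7,0.8,0.12,0.82,0.8,0.12,0.82
8,0.72,0.2,0.79,0.72,0.2,0.79
9,0.79,0.18,0.8,0.79,0.18,0.8
10,0.8,0.13,0.8,0.8,0.13,0.8
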