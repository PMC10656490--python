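variant_id,value,censor,replicate
1,0.58,none,run1
2,0,none,run1
3,0.09,none,run1
4,S,,run1
5,0.09,none,run1
6,S,,run1
7,0.84,none,run1
8,S,,run1
9,0,none,run1
10,0.15,none,run1
1,1.38,none,run2
2,0,none,run2
3,0.16,none,run2
4,S,,run2
5,0.07,none,run2
6,S,,run2
7,0.82,none,run2
8,S,,run2
9,0,none,run2
10,0.12,none,run2
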