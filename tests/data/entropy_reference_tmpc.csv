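descriptor,k,m,entropy
M1,1,1,2.703
M1,1,2,3.11
M1,1,3,3.384
M1,1,4,3.59
M1,2,1,2.86
M1,2,2,3.271
M1,2,3,3.465
M1,2,4,3.754
M1,3,1,2.815
M1,3,2,3.256
M1,3,3,3.543
M1,3,4,3.757
M2,1,1,2.76
M2,1,2,3.157
M2,1,3,3.426
M2,1,4,3.63
M2,2,1,3.07
M2,2,2,3.477
M2,2,3,3.622
M2,2,4,3.956
M2,3,1,2.978
M2,3,2,3.441
M2,3,3,3.735
M2,3,4,3.953
F,1,1,3.077
F,1,2,3.478
F,1,3,3.748
F,1,4,3.953
F,2,1,3.374
F,2,2,3.786
F,2,3,3.936
F,2,4,4.267
F,3,1,3.359
F,3,2,3.818
F,3,3,4.11
F,3,4,4.327
HZ,1,1,3.36
HZ,1,2,3.765
HZ,1,3,4.037
HZ,1,4,4.242
HZ,2,1,3.661
HZ,2,2,4.078
HZ,2,3,4.228
HZ,2,4,4.561
HZ,3,1,3.611
HZ,3,2,4.079
HZ,3,3,4.374
HZ,3,4,4.592
ReZ3,1,1,3.428
ReZ3,1,2,3.823
ReZ3,1,3,4.089
ReZ3,1,4,4.292
ReZ3,2,1,3.875
ReZ3,2,2,4.288
ReZ3,2,3,4.416
ReZ3,2,4,4.768
ReZ3,3,1,3.81
ReZ3,3,2,4.296
ReZ3,3,3,4.597
ReZ3,3,4,4.818
BM,1,1,3.028
BM,1,2,3.434
BM,1,3,3.705
BM,1,4,3.911
BM,2,1,3.272
BM,2,2,3.685
BM,2,3,3.851
BM,2,4,4.167
BM,3,1,3.2
BM,3,2,3.658
BM,3,3,3.95
BM,3,4,4.167
TM,1,1,3.242
TM,1,2,3.645
TM,1,3,3.916
TM,1,4,4.121
TM,2,1,3.541
TM,2,2,3.957
TM,2,3,4.106
TM,2,4,4.439
TM,3,1,3.504
TM,3,2,3.968
TM,3,3,4.262
TM,3,4,4.48
BMH,1,1,3.395
BMH,1,2,3.795
BMH,1,3,4.064
BMH,1,4,4.267
BMH,2,1,3.781
BMH,2,2,4.196
BMH,2,3,4.333
BMH,2,4,4.677
BMH,3,1,3.723
BMH,3,2,4.201
BMH,3,3,4.5
BMH,3,4,4.72
TMH,1,1,3.612
TMH,1,2,4.011
TMH,1,3,4.279
TMH,1,4,4.482
TMH,2,1,4.052
TMH,2,2,4.469
TMH,2,3,4.601
TMH,2,4,4.951
TMH,3,1,4.025
TMH,3,2,4.509
TMH,3,3,4.809
TMH,3,4,5.029
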