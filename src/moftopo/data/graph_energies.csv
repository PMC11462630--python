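family,m,n,energy
TM-Pc,1,1,133.489
TM-Pc,1,2,210.027
TM-Pc,1,3,286.562
TM-Pc,2,2,329.709
TM-Pc,2,3,449.389
TM-Pc,3,3,612.212
MOAPc,1,1,298.584
MOAPc,1,2,446.769
MOAPc,1,3,594.955
MOAPc,2,2,668.495
MOAPc,2,3,890.221
MOAPc,3,3,1185.487
MBHT,1,1,118.364
MBHT,1,2,196.369
MBHT,1,3,274.374
MBHT,2,2,312.924
MBHT,2,3,429.479
MBHT,3,3,584.584
NHC-TM,1,1,202.508
NHC-TM,1,2,302.791
NHC-TM,1,3,403.073
NHC-TM,2,2,452.234
NHC-TM,2,3,602.009
NHC-TM,3,3,800.796
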