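grade,presentations,n_le10,n_11_15,n_16_20,n_21_25,n_total
1,FE,32,48,65,84,229
1,DD,6,7,17,24,54
1,FE+DD,1,4,12,21,38
2,PMD+MER,0,0,4,14,18
2,MER+MED,0,0,2,7,9
2,PMD+MER+MED,0,0,0,5,5
3,PE,0,0,1,1,2
3,PE+CMD,0,0,0,5,5
interruption,,0,0,2,2,4
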