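grade,during_n,post_n
1,321,210
2,32,97
3,7,37
4,0,16
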