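category,n
IIA,36
IIB,107
IIIA,99
IIIB,32
IIIC,86
total,360
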