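cluster,other,adr
0,732,157
1,412,29
2,321,3
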