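code
0250
0270
0300
0320
0360
0420
0450
0510
0636
0730
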