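# toy network A (synthetic, hand-written)
p1 p2
p2 p3
p3 p1
p3 p4
p4 p5
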