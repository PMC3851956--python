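# synthetic toy ortholog pairs
p1 q1
p3 q3
p5 q6
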