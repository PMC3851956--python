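# toy network B (synthetic, hand-written)
q1 q2
q2 q3
q3 q1
q3 q4
q4 q5
q5 q6
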