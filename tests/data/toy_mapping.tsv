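p1	q1
p2	q2
p3	q3
p4	q4
p5	q5
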