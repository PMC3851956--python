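# node	term	domain	depth  (synthetic toy annotations)
p1 GO:0001 BP 5
p1 GO:0002 MF 4
p2 GO:0001 BP 5
p3 GO:0003 CC 3
p4 GO:0004 BP 2
p5 GO:0005 MF 6
q1 GO:0001 BP 5
q2 GO:0001 BP 5
q2 GO:0002 MF 4
q3 GO:0003 CC 3
q4 GO:0004 BP 2
q5 GO:0005 MF 6
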