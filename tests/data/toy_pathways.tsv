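# pathway	side	node  (synthetic toy pathway membership)
path1 A p1
path1 A p2
path1 A p3
path1 B q1
path1 B q2
path1 B q3
path2 A p4
path2 A p5
path2 B q4
path2 B q5
path2 B q6
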