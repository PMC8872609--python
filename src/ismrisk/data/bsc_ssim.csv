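,R98,R7,R100,R102,R67,R13,R40,R11,R35,R62,R49,R1,R5,R63,R16,R20,R87
R98,,X,X,X,V,V,V,V,O,O,V,V,X,O,V,V,A
R7,X,,V,A,O,X,O,V,O,O,X,O,X,O,V,O,A
R100,X,A,,V,V,V,O,V,V,A,V,V,X,O,V,V,A
R102,X,V,A,,V,V,V,V,V,O,V,V,X,O,V,A,A
R67,A,O,A,A,,V,V,V,V,A,V,V,V,A,O,V,O
R13,A,X,A,A,A,,V,V,V,A,O,O,O,A,V,A,A
R40,A,O,O,A,A,A,,A,A,O,A,A,A,O,A,A,A
R11,A,A,A,A,A,A,V,,V,A,V,O,0,A,V,A,A
R35,O,O,A,A,A,A,V,A,,O,A,A,A,O,A,A,A
R62,O,O,V,O,V,V,O,V,O,,V,O,O,V,O,V,O
R49,A,X,A,A,A,O,V,A,V,A,,O,O,A,O,A,A
R1,A,O,A,A,A,O,V,O,V,O,O,,A,O,O,O,O
R5,X,X,X,X,A,O,V,0,V,O,O,V,,O,O,A,O
R63,O,O,O,O,V,V,O,V,O,A,V,O,O,,O,V,O
R16,A,A,A,A,O,A,V,A,V,O,O,O,O,O,,O,A
R20,A,O,A,V,A,V,V,V,V,A,V,O,V,A,O,,A
R87,V,V,V,V,O,V,V,V,V,O,V,O,O,O,V,V,
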