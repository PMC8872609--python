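code,degree
R1,37
R2,19
R3,8
R4,27
R5,39
R6,30
R7,39
R8,29
R9,31
R10,25
R11,38
R12,29
R13,39
R14,13
R15,26
R16,37
R17,16
R18,21
R19,9
R20,37
R21,16
R22,31
R23,19
R24,5
R25,19
R26,23
R27,23
R28,23
R29,23
R30,17
R31,24
R32,24
R33,31
R34,30
R35,36
R36,34
R37,12
R38,32
R39,32
R40,37
R41,22
R42,25
R43,27
R44,13
R45,19
R46,33
R47,14
R48,30
R49,37
R50,14
R51,28
R52,12
R53,33
R54,33
R55,10
R56,20
R57,26
R58,14
R59,32
R60,25
R61,29
R62,36
R63,36
R64,17
R65,10
R66,30
R67,37
R68,30
R69,34
R70,29
R71,31
R72,17
R73,28
R74,13
R75,11
R76,20
R77,18
R78,11
R79,7
R80,9
R81,10
R82,15
R83,33
R84,15
R85,26
R86,34
R87,38
R88,31
R89,30
R90,22
R91,30
R92,28
R93,16
R94,26
R95,33
R96,18
R97,12
R98,51
R99,8
R100,38
R101,31
R102,38
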