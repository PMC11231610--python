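>FABP3 heart-type fatty acid binding protein, human (UniProt P05413)
MVDAFLGTWKLVDSKNFDDYMKSLGVGFATRQVASMTKPTTIIEKNGDILTLKTHSTFKN
TEISFKLGVEFDETTADDRKVKSIVTLDGGKLVHLQKWDGQETTLVRELIDGKLILTLTH
GTAVCTRTYEKEA
>FABP4 adipocyte-type fatty acid binding protein, human (UniProt P15090)
MCDAFVGTWKLVSSENFDDYMKEVGVGFATRKVAGMAKPNMIISVNGDLVTIRSESTFKN
TEISFILGQEFDEVTADDRKVKSIITLDGGVLVHVQKWDGKSTTIKRKREDDKLVVECVM
KGVTSTRVYERA
>FABP5 epidermal fatty acid binding protein, human (UniProt Q01469)
MATVQQLEGRWRLVDSKGFDEYMKELGVGIALRKMGAMAKPDCIITCDGKNLTIKTESTL
KTTQFSCTLGEKFEETTADGRKTQTVCNFTDGALVQHQEWDGKESTITRKLKDGKLVVEC
VMNNVTCTRIYEKVE
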