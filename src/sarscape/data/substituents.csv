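name,prefix,suffix,effect
none,,,0.0
methyl,C,C,0.10
ethyl,CC,CC,0.15
propyl,CCC,CCC,0.05
hydroxy,O,O,0.40
methoxy,CO,OC,0.20
amino,N,N,0.50
fluoro,F,F,0.25
chloro,Cl,Cl,0.30
bromo,Br,Br,0.20
trifluoromethyl,FC(F)(F),C(F)(F)F,-0.30
nitrile,N#C,C#N,-0.20
carboxy,OC(=O),C(=O)O,0.80
carbamoyl,NC(=O),C(=O)N,0.60
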