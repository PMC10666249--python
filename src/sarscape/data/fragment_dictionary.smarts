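# sarscape substructure fragment dictionary v1 (512 SMARTS, one per line)
[#5]
[#7]
[#8]
[#9]
[#14]
[#15]
[#16]
[#17]
[#35]
[#53]
[F,Cl,Br,I]
[+]
[-]
c
n
o
[CX4]
[CX3]
[CX2]
[NX3]
[NX2]
[NX1]
[OX2]
[OX1]
[#6;R]
[#7;R]
[#8;R]
[#16;R]
C-C
C=C
C#C
C-N
C=N
C#N
C-O
C=O
C-S
C=S
C-P
N-N
N=N
N-O
N=O
N-S
O-S
O-P
S=O
N-P
cc
cn
co
cs
nn
c:n:c
n:c:n
C=C-C=C
C=C-C=O
c-C
c-N
c-O
c-S
c-c
CC
CCC
CCCC
CCCCC
CCCCCC
CCCCCCC
CCCCCCCC
[CX3]=[OX1]
[CX3](=O)[OX2H1]
[CX3](=O)[OX1-]
[CX3](=O)O[#6]
[CX3](=O)[NX3]
[CX3H1]=O
[CX3](=O)[#6]
O=C([NX3])[NX3]
[NX3][CX3](=O)O[#6]
O=C1CCCN1
O=C1CCCCN1
[NX3;H2][#6]
[NX3;H1]([#6])[#6]
[NX3]([#6])([#6])[#6]
[NX3+0](=O)=O
[NX1]#[CX2]
[NX2]=[NX2]
[NX3][NX3]
[NX2]=[CX3]
NC(=N)N
[#6]C(=N)N
[NX3][OX2H1]
[NX2]=[OX1]
[nH]
[NX4+]
[NX3+]=[CX3]
[OX2H]
[OX2H][CX4]
[OX2H]c
[OX2]([#6])[#6]
[OX2H][CX3]=[OX1]
[#6][OX2][#6]=O
C1CO1
[OX1-]
[SX2H]
[SX2]([#6])[#6]
[SX3]=[OX1]
[SX4](=[OX1])(=[OX1])
[SX4](=O)(=O)[NX3]
[SX4](=O)(=O)[OX2H1]
[#16X2][#16X2]
s
[PX4](=[OX1])
[PX4](=O)([OX2])([OX2])
P
[#6]F
[#6]Cl
[#6]Br
[#6]I
cF
cCl
cBr
cI
C(F)(F)F
[CX4](F)F
[#6]=[#6][CX3]=[OX1]
[OX2H][#6][#6][NX3]
[NX3][#6][CX3](=O)[OX2H1]
[#6](=O)[#6][#6](=O)
c-[NX3]
c-[OX2H]
c-[CX3]=[OX1]
c[CX4]
c-[SX2]
c-[NX3](=O)=O
cC#N
C=C=C
C#CC
[OX2][CX4][OX2]
[SX2][CX3]=[OX1]
[NX3]S(=O)=O
[#6]=[#7][#7]
[OX2][NX2]=[#6]
[F][CX4][F]
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CCCCCC1
C1CCCCCCC1
C1=CCCCC1
C1=CCCC1
c1ccccc1
C1CCNC1
C1CCNCC1
C1CCOC1
C1CCOCC1
C1CCSC1
C1CCSCC1
C1CNCCN1
C1COCCN1
C1CCNCCC1
N1CCNCC1
C1OCCO1
C1OCOC1
c1cc[nH]c1
c1ccoc1
c1ccsc1
c1cnc[nH]1
c1cn[nH]c1
c1ccncc1
c1ccnnc1
c1cncnc1
c1cnncn1
a1aaaa1
a1aaaaa1
c1ccc2ccccc2c1
c1ccc2[nH]ccc2c1
c1ccc2occc2c1
c1ccc2sccc2c1
c1ccc2ncccc12
c1ccc2[nH]cnc2c1
c1ccc2OCOc2c1
C1CCc2ccccc2C1
C1Cc2ccccc2C1
C1CCC2CCCCC2C1
O=c1cccc[nH]1
[r3]
[r4]
[r5]
[r6]
[r7]
[r8]
[R2]
C(C)C
C(C)(C)C
C(C)(C)(C)C
C(N)N
C(O)O
N(C)C
C(c)c
c(c)(c)c
C(F)F
C(Cl)Cl
[CX4][CX4]
[CX4][CX3]
[CX3][CX3]
[CX4][NX3]
[CX3][NX3]
[CX4][OX2]
[CX3][OX2]
[CX4][SX2]
[CX4]c
[CX3]c
[NX3]c
[OX2]c
[CX2][CX4]
[CX2]c
CCN
CCO
CCS
CNC
CNN
CNO
CNS
COC
CON
COO
COS
CSC
CSN
CSO
CSS
NCN
NCO
NCS
NNN
NNO
NNS
NON
NOO
NOS
NSN
NSO
NSS
OCO
OCS
ONO
ONS
OOO
OOS
OSO
OSS
SCS
SNS
SOS
SSS
CCCN
CCCO
CCCS
CCNC
CCNN
CCNO
CCNS
CCOC
CCON
CCOO
CCOS
CCSC
CCSN
CCSO
CCSS
CNCN
CNCO
CNCS
CNNC
CNNN
CNNO
CNNS
CNOC
CNON
CNOO
CNOS
CNSC
CNSN
CNSO
CNSS
COCN
COCO
COCS
CONN
CONO
CONS
COOC
COON
COOO
COOS
COSC
COSN
COSO
COSS
CSCN
CSCO
CSCS
CSNN
CSNO
CSNS
CSON
CSOO
CSOS
CSSC
CSSN
CSSO
CSSS
NCCN
NCCO
NCCS
NCNN
NCNO
NCNS
NCON
NCOO
NCOS
NCSN
NCSO
NCSS
NNCO
NNCS
NNNN
NNNO
NNNS
NNON
NNOO
NNOS
NNSN
NNSO
NNSS
NOCO
NOCS
NONO
NONS
NOON
NOOO
NOOS
NOSN
NOSO
NOSS
NSCO
NSCS
NSNO
NSNS
NSOO
NSOS
NSSN
NSSO
NSSS
OCCO
OCCS
OCNO
OCNS
OCOO
OCOS
OCSO
OCSS
ONCS
ONNO
ONNS
ONOO
ONOS
ONSO
ONSS
OOCS
OONS
OOOO
OOOS
OOSO
OOSS
OSCS
OSNS
OSOS
OSSO
OSSS
SCCS
SCNS
SCOS
SCSS
SNNS
SNOS
SNSS
SOOS
SOSS
SSSS
[#6]~*~[#6]
[#6]~*~[#7]
[#6]~*~[#8]
[#6]~*~[#16]
[#6]~*~[#9]
[#6]~*~[#17]
[#6]~*~[#35]
[#7]~*~[#7]
[#7]~*~[#8]
[#7]~*~[#16]
[#7]~*~[#9]
[#7]~*~[#17]
[#7]~*~[#35]
[#8]~*~[#8]
[#8]~*~[#16]
[#8]~*~[#9]
[#8]~*~[#17]
[#8]~*~[#35]
[#16]~*~[#16]
[#16]~*~[#9]
[#16]~*~[#17]
[#16]~*~[#35]
[#9]~*~[#9]
[#9]~*~[#17]
[#9]~*~[#35]
[#17]~*~[#17]
[#17]~*~[#35]
[#35]~*~[#35]
[#6]~*~*~[#6]
[#6]~*~*~[#7]
[#6]~*~*~[#8]
[#6]~*~*~[#16]
[#6]~*~*~[#9]
[#6]~*~*~[#17]
[#6]~*~*~[#35]
[#7]~*~*~[#7]
[#7]~*~*~[#8]
[#7]~*~*~[#16]
[#7]~*~*~[#9]
[#7]~*~*~[#17]
[#7]~*~*~[#35]
[#8]~*~*~[#8]
[#8]~*~*~[#16]
[#8]~*~*~[#9]
[#8]~*~*~[#17]
[#8]~*~*~[#35]
[#16]~*~*~[#16]
[#16]~*~*~[#9]
[#16]~*~*~[#17]
[#16]~*~*~[#35]
[#9]~*~*~[#9]
[#9]~*~*~[#17]
[#9]~*~*~[#35]
[#17]~*~*~[#17]
[#17]~*~*~[#35]
[#35]~*~*~[#35]
[#6]~*~*~*~[#6]
[#6]~*~*~*~[#7]
[#6]~*~*~*~[#8]
[#6]~*~*~*~[#16]
[#6]~*~*~*~[#9]
[#6]~*~*~*~[#17]
[#6]~*~*~*~[#35]
[#7]~*~*~*~[#7]
[#7]~*~*~*~[#8]
[#7]~*~*~*~[#16]
[#7]~*~*~*~[#9]
[#7]~*~*~*~[#17]
[#7]~*~*~*~[#35]
[#8]~*~*~*~[#8]
[#8]~*~*~*~[#16]
[#8]~*~*~*~[#9]
[#8]~*~*~*~[#17]
[#8]~*~*~*~[#35]
[#16]~*~*~*~[#16]
[#16]~*~*~*~[#9]
[#16]~*~*~*~[#17]
[#16]~*~*~*~[#35]
[#9]~*~*~*~[#9]
[#9]~*~*~*~[#17]
[#9]~*~*~*~[#35]
[#17]~*~*~*~[#17]
[#17]~*~*~*~[#35]
[#35]~*~*~*~[#35]
c~a~c
c~a~a~c
c~a~a~a~c
c~a~n
c~a~a~n
c~a~a~a~n
c~a~o
c~a~a~o
c~a~a~a~o
c~a~s
c~a~a~s
c~a~a~a~s
n~a~n
n~a~a~n
n~a~a~a~n
n~a~o
n~a~a~o
n~a~a~a~o
n~a~s
n~a~a~s
n~a~a~a~s
o~a~o
o~a~a~o
o~a~a~a~o
o~a~s
o~a~a~s
o~a~a~a~s
s~a~s
s~a~a~s
s~a~a~a~s
[#7]~*~*~*~*~[#7]
[#7]~*~*~*~*~[#8]
[#7]~*~*~*~*~[#16]
[#7]~*~*~*~*~[#9]
[#7]~*~*~*~*~[#17]
[#8]~*~*~*~*~[#8]
[#8]~*~*~*~*~[#16]
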