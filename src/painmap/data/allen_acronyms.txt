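# Common Allen Mouse Brain Atlas structure acronyms (hand-assembled
# synthetic convenience list for name validation; not the full ontology).
ACA
ACAd
ACAv
ACB
AD
AI
AId
AIp
AIv
AMB
AON
AP
APN
ARH
AUD
AUDd
AUDp
AUDv
AV
BLA
BMA
BST
CA1
CA2
CA3
CEA
CL
CLA
CM
COA
CP
CS
CUN
DG
DMH
DR
ECT
ENTl
ENTm
EP
FRP
FS
GPe
GPi
GU
HPF
IAD
IC
ILA
IO
LA
LC
LD
LGd
LGv
LH
LHA
LP
LPO
LS
MA
MD
MEA
MG
MM
MOB
MOp
MOs
MPN
MPO
MRN
MS
NDB
NLL
NTS
OP
ORB
ORBl
ORBm
ORBvl
OT
PA
PAG
PAL
PB
PERI
PF
PG
PH
PIR
PL
PO
POST
PP
PPN
PRE
PRNc
PRNr
PSV
PT
PVH
PVT
RE
RH
RN
RSP
RSPagl
RSPd
RSPv
RT
SC
SCm
SCs
SI
SMT
SNc
SNr
SO
SPF
SSp
SSs
SUB
SUM
TEa
TH
TR
TT
TU
V
VAL
VISal
VISam
VISl
VISp
VISpm
VM
VMH
VPL
VPM
VTA
ZI
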