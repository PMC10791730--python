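PreCG.L
PreCG.R
SFGdor.L
SFGdor.R
ORBsup.L
ORBsup.R
MFG.L
MFG.R
ORBmid.L
ORBmid.R
IFGoperc.L
IFGoperc.R
IFGtriang.L
IFGtriang.R
ORBinf.L
ORBinf.R
ROL.L
ROL.R
SMA.L
SMA.R
OLF.L
OLF.R
SFGmed.L
SFGmed.R
ORBsupmed.L
ORBsupmed.R
REC.L
REC.R
INS.L
INS.R
ACG.L
ACG.R
DCG.L
DCG.R
PCG.L
PCG.R
HIP.L
HIP.R
PHG.L
PHG.R
AMYG.L
AMYG.R
CAL.L
CAL.R
CUN.L
CUN.R
LING.L
LING.R
SOG.L
SOG.R
MOG.L
MOG.R
IOG.L
IOG.R
FFG.L
FFG.R
PoCG.L
PoCG.R
SPG.L
SPG.R
IPL.L
IPL.R
SMG.L
SMG.R
ANG.L
ANG.R
PCUN.L
PCUN.R
PCL.L
PCL.R
CAU.L
CAU.R
PUT.L
PUT.R
PAL.L
PAL.R
THA.L
THA.R
HES.L
HES.R
STG.L
STG.R
TPOsup.L
TPOsup.R
MTG.L
MTG.R
TPOmid.L
TPOmid.R
ITG.L
ITG.R
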