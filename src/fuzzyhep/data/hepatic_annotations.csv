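name,role,measured,perturbable,constitutive
IL6,stimulus,False,False,False
IL6R,signaling,False,False,False
JAK1,signaling,False,False,False
STAT3,signaling,False,True,False
SHP2,signaling,False,False,False
RAS,signaling,False,False,False
RAF1,signaling,False,False,False
MEK,signaling,False,True,False
ERK,signaling,False,False,False
PI3K,signaling,False,True,False
AKT,signaling,False,False,False
IKK,signaling,False,False,False
NFKB,transcription_factor,False,False,False
SOCS1,signaling,False,False,False
RXRNR,complex,False,False,False
GR,transcription_factor,False,False,False
AHR,transcription_factor,False,False,False
ELK1,transcription_factor,False,False,False
CFOS,transcription_factor,False,False,False
HNF4A,transcription_factor,False,False,False
HNF1A,transcription_factor,False,False,True
CRP,gene,True,False,False
SAA1,gene,True,False,False
SAA2,gene,True,False,False
SOCS3,gene,True,False,False
CYP1A2,gene,True,False,False
CYP2A6,gene,True,False,False
CYP2B6,gene,True,False,False
CYP2C8,gene,True,False,False
CYP2C9,gene,True,False,False
CYP2C19,gene,True,False,False
CYP2D6,gene,True,False,False
CYP2E1,gene,True,False,False
CYP3A4,gene,True,False,False
CYP7A1,gene,True,False,False
ABCB1,gene,True,False,False
ABCB11,gene,True,False,False
ABCC2,gene,True,False,False
ABCG2,gene,True,False,False
SLC10A1,gene,True,False,False
SLC22A1,gene,True,False,False
SLCO1B1,gene,True,False,False
UGT1A1,gene,True,False,False
UGT2B7,gene,True,False,False
GSTA2,gene,True,False,False
GSTM1,gene,True,False,False
NAT1,gene,True,False,False
NAT2,gene,True,False,False
SULT1A1,gene,True,False,False
TPMT,gene,True,False,False
FMO3,gene,True,False,False
CES1,gene,True,False,False
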