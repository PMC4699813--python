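# Curated hepatic IL-6 prior knowledge network (approximate transcription of
# a published pathway figure; intended as a worked example, not a reference).
# Signal transduction
IL6	1	IL6R
IL6R	1	JAK1
JAK1	1	STAT3
IL6R	1	SHP2
SHP2	1	RAS
RAS	1	RAF1
RAF1	1	MEK
MEK	1	ERK
SHP2	1	PI3K
PI3K	1	AKT
AKT	1	IKK
IKK	1	NFKB
# Negative feedback (removed before modeling; see hepatic_feedback_removals.csv)
STAT3	1	SOCS1
SOCS1	-1	JAK1
SOCS3	-1	JAK1
# Signaling onto transcription factors / nuclear receptor complexes
ERK	-1	RXRNR
NFKB	-1	RXRNR
ERK	-1	GR
ERK	1	ELK1
ERK	1	CFOS
NFKB	-1	AHR
NFKB	-1	HNF4A
# Acute-phase gene induction
STAT3	1	CRP
STAT3	1	SAA1
STAT3	1	SAA2
STAT3	1	SOCS3
# Nuclear-receptor-dependent detoxification genes
RXRNR	1	CYP2A6
RXRNR	1	CYP2B6
RXRNR	1	CYP2C8
RXRNR	1	CYP2D6
RXRNR	1	CYP3A4
RXRNR	1	CYP7A1
RXRNR	1	ABCB11
RXRNR	1	ABCC2
RXRNR	1	SLC22A1
RXRNR	1	UGT1A1
RXRNR	1	UGT2B7
RXRNR	1	FMO3
AHR	1	CYP1A2
GR	1	GSTA2
GR	1	TPMT
GR	1	ABCG2
HNF4A	1	CYP2C9
HNF4A	1	CYP2C19
HNF4A	1	NAT2
HNF4A	1	SULT1A1
HNF1A	1	SLCO1B1
HNF1A	1	SLC10A1
NFKB	-1	ABCB1
NFKB	-1	SLC10A1
NFKB	-1	NAT1
CFOS	1	CYP2E1
ELK1	1	CES1
NFKB	-1	GSTM1
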