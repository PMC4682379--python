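# The 28 core network marker proteins shared by bladder, colorectal,
# liver and lung cancer, one gene symbol per line.
BRCA1
CDK2
CEBPB
CREBBP
CTNNB1
CUL1
CUL3
EP300
ESR1
HDAC1
HDAC2
HDAC4
IRAK1
ISG15
KIAA0101
MDM2
MYC
PCNA
PRKDC
PSMA3
RB1
SRC
TERF1
TP53
TRAF2
UBC
XRCC6
YWHAZ
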