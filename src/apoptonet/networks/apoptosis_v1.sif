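# Curated neuronal apoptosis network: 21 vertices, 37 signed interactions.
# Death-receptor arm
FASL	+	CASP8
CFLIP	-	CASP8
CASP3	+	CASP8
CASP8	+	BID
# Mitochondrial (type II) arm
BID	+	BAX
BID	+	CYTC
BID	+	SMAC
BAD	+	BAX
BCL2	-	BAX
BCL2	-	CYTC
BCL2	-	SMAC
P53	+	BAX
BAX	+	CYTC
BAX	+	SMAC
CYTC	+	APAF
# Apoptosome and executioner caspases
APAF	+	CASP9
IAP	-	CASP9
CASP9	+	CASP3
IAP	-	CASP3
CASP3	-	IAP
SMAC	-	IAP
NFKB	+	IAP
# Growth-factor survival arm
GF	+	AKT
AKT	-	BAD
NFKB	+	BCL2
BAD	-	BCL2
P53	-	BCL2
AKT	+	IKK
IKK	-	IKB
IKB	-	NFKB
NFKB	+	CFLIP
# DNA damage / p53 axis
AKT	+	MDM2
P53	+	MDM2
CASP3	+	DNADAM
CYTC	+	DNADAM
DNADAM	+	P53
P53	-	P53
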