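# Module-family membership of microtubule inner proteins in C. reinhardtii
# ("Chlamydomonas") and H. sapiens ("Human"), transcribed cell-by-cell from the
# published summary table of the seven MT-binding module families.
# evidence_source: profile-HMM (iterative HMM-to-HMM searches), Gibbs (weight-
# matrix / Gibbs sampler prediction), inferred-3D (single Mn units inferred by
# visual inspection of outer-doublet coordinates).
# Transcription notes (garbled cells resolved against the running text and
# figure legends):
#  - The Chlamydomonas SNYG paralog list is taken as FAP85, FAP90, FAP144,
#    FAP182, FAP183 (five Chlamydomonas SNYG proteins per the discussion text;
#    the table cell interleaves human FAM183A into the list).
#  - Human NWE-module membership comprises the four triad-bearing proteins
#    (CFAP95, CFAP107, SPAG8, CFAP68) plus the NWE-only CFAP161 — five human
#    proteins as in the NWE alignment figure legend.
#  - Human SNYG membership is the eight proteins of the SNYG alignment figure.
#  - Aliases in parentheses in the published table are kept in the alias column.
family	species	protein	alias	evidence_source
DM10	Chlamydomonas	FAP67		profile-HMM
DM10	Chlamydomonas	RIB72		profile-HMM
DM10	Chlamydomonas	XP_001691061		profile-HMM
DM10	Human	EFHC1		profile-HMM
DM10	Human	EFHC2		profile-HMM
DM10	Human	NME7		profile-HMM
DM10	Human	CAPS2		profile-HMM
Mn	Chlamydomonas	FAP363		profile-HMM
Mn	Chlamydomonas	FAP257		profile-HMM
Mn	Chlamydomonas	FAP203		profile-HMM
Mn	Chlamydomonas	FAP236		profile-HMM
Mn	Chlamydomonas	FAP273		inferred-3D
Mn	Chlamydomonas	RIB21		inferred-3D
Mn	Chlamydomonas	FAP166		inferred-3D
Mn	Human	MAP6		profile-HMM
Mn	Human	MAP6D1		profile-HMM
Mn	Human	SAXO1		profile-HMM
Mn	Human	SAXO2		profile-HMM
Mn	Human	TEX45	SAXO5	profile-HMM
Mn	Human	TEX26		profile-HMM
Mn	Human	C2ORF73		profile-HMM
Mn	Human	MDM1		Gibbs
Mn	Human	TEX36		Gibbs
Mn	Human	TEX37	SPMIP9	Gibbs
Mn	Human	C3ORF84		Gibbs
Mn	Human	C1ORF100	SPMIP3	Gibbs
Mn	Human	SMRP1	SPMIP6	Gibbs
NWE	Chlamydomonas	FAP95		profile-HMM
NWE	Chlamydomonas	FAP107		profile-HMM
NWE	Chlamydomonas	FAP143		profile-HMM
NWE	Chlamydomonas	FAP68		profile-HMM
NWE	Chlamydomonas	FAP161		profile-HMM
NWE	Human	C9ORF135	CFAP95	profile-HMM
NWE	Human	C1ORF158	CFAP107	profile-HMM
NWE	Human	SPAG8		profile-HMM
NWE	Human	C11ORF1	CFAP68	profile-HMM
NWE	Human	CFAP161		profile-HMM
PYG	Chlamydomonas	FAP129		profile-HMM
PYG	Chlamydomonas	FAP252		profile-HMM
PYG	Chlamydomonas	FAP222		profile-HMM
PYG	Chlamydomonas	XP_001689677		profile-HMM
PYG	Human	FAM166A	CIMIP2B	profile-HMM
PYG	Human	FAM166B	CIMIP2B	profile-HMM
PYG	Human	FAM166C	CIMIP2C	profile-HMM
PYG	Human	C10ORF82	SPMIP5	profile-HMM
PYG	Human	SPATA48	SPMIP7	profile-HMM
SNYG	Chlamydomonas	FAP85		profile-HMM
SNYG	Chlamydomonas	FAP90		profile-HMM
SNYG	Chlamydomonas	FAP144		profile-HMM
SNYG	Chlamydomonas	FAP182		profile-HMM
SNYG	Chlamydomonas	FAP183		profile-HMM
SNYG	Human	PIERCE1		profile-HMM
SNYG	Human	PIERCE2		profile-HMM
SNYG	Human	C5ORF49	CFAP90	profile-HMM
SNYG	Human	FAM183A	CFAP144	profile-HMM
SNYG	Human	C20ORF85	CIMIP1	profile-HMM
SNYG	Human	C2ORF50		profile-HMM
SNYG	Human	ATP6V1FNB	SPMIP1	profile-HMM
SNYG	Human	TEX49	SPMIP11	profile-HMM
GFG	Chlamydomonas	FAP77		profile-HMM
GFG	Chlamydomonas	FAP21		profile-HMM
GFG	Human	EFHB		profile-HMM
GFG	Human	CFAP77		profile-HMM
ELLEn	Chlamydomonas	FAP53		profile-HMM
ELLEn	Chlamydomonas	FAP141		profile-HMM
ELLEn	Human	CFAP53		profile-HMM
ELLEn	Human	CFAP141		profile-HMM
ELLEn	Human	TCHP		profile-HMM
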