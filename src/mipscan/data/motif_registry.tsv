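# Motif grammar registry for microtubule inner protein (MIP) modules.
# Syntax strings for MN_UNIT, NWE, SNYG and ELLEN are the published grammars
# verbatim; the Phi placeholder of the ELLEn prose is already spelled out as
# explicit [LIVMFY]/[LIVFMY] classes inside the printed syntax.
# PYG and GFG are reconstructions: the published consensus names the conserved
# residues (Pro-Tyr-Gly; Gly-Phe-Gly) but prints no spacing string, so the
# registry encodes PYG as a gapped triplet and GFG as the bare triplet, with
# array spacing handled downstream by the module caller.
name	syntax	status	note
MN_UNIT	[TS]-[TS]-X(4)-[YF]	published	minimal Mn repeat unit signature; ~7-residue MT-binding alpha-helix
NWE	[ILV]-L-I-G-N-W-X-E	published	N-terminal seam-binding motif of the NWE module
SNYG	[ST]-N-X-X-[ILVY]-G	published	divergent Mn-like motif with invariant glycine
ELLEN	[LIV]-X(3,4)-[RK]-X(23,29)-[W]-X(24,31)-[LIV]-X(2)-R-X(3)-[LIV]-X(2)-[LIVMFY]-[LIVMFY]-X(2)-E-X(3)-[LIVFMY]-X(2)-E	published	ELLEn module grammar; computed span bounds 75-89 residues
PYG	P-X(0,2)-Y-X(0,2)-G	reconstructed	gapped Pro-Tyr-Gly triplet; unit spacing 20-60 residues in arrays
GFG	G-F-G	reconstructed	Gly-Phe-Gly signature; ~31-residue tandem unit along the protofilament
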