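# Default colorectal-cancer actionability rule table (OncoKB-style levels).
# Levels: L1 FDA-approved biomarker, L3 clinical evidence, L4 laboratory
# evidence, R1 resistance to an FDA-approved drug. Codon targets match the
# reference amino acid + residue number regardless of the substituting allele.
# Rows whose drug is marked "(synthetic placeholder)" stand in for
# non-public laboratory-evidence listings; replace with a curated table
# for real use.
gene	match_mode	targets	drug	direction	level
KRAS	codon_set	G12,G13	Cetuximab	resistance	R1
KRAS	codon_set	Q61,K117,A146	Cetuximab	resistance	R1
NRAS	codon_set	Q61	Panitumumab	resistance	R1
NRAS	codon_set	G12,G13	Panitumumab	resistance	R1
BRAF	exact_protein_change	V600E	Encorafenib	sensitivity	L1
KRAS	exact_protein_change	G12C	Adagrasib	sensitivity	L3
KRAS	codon_set	G12,G13,Q61	MEK-inhibitor combination (synthetic placeholder)	sensitivity	L4
PIK3CA	codon_set	E542,E545,H1047	PI3K-alpha inhibitor (synthetic placeholder)	sensitivity	L4
NF1	any_nonsynonymous		MEK inhibitor (synthetic placeholder)	sensitivity	L4
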