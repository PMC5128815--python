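gene	alteration_class	therapy	indication	phase	requires_her2_positive
PIK3CA	snv	PI3K pathway inhibitor	breast	early
PIK3CA	snv	PI3K alpha inhibitor	breast	early
PIK3CA	snv	AKT inhibitor	breast	early
PIK3CA	snv	everolimus + trastuzumab + chemotherapy	breast	late	yes
TOP2A	amplification	anthracycline	breast	late	yes
FGF3	amplification	dovitinib	breast	early
FGF4	amplification	dovitinib	breast	early
FGFR1	amplification	FGFR inhibitor	breast	early
ERBB2	amplification	trastuzumab	breast	approved
ERBB2	snv	neratinib	breast	early
BRCA1	snv	PARP inhibitor	breast	late
BRCA2	snv	PARP inhibitor	breast	late
AKT1	snv	AKT inhibitor	breast	early
CCND1	amplification	CDK4/6 inhibitor	other	late
EGFR	snv	erlotinib	other	approved
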