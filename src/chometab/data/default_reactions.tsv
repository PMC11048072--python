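id	equation	lower_bound	upper_bound	subsystem	is_exchange	is_measured
EX_glc	glc_e <->	-1000	1000	transport	1	1
EX_lac	lac_e <->	-1000	1000	transport	1	1
EX_nh4	nh4_e <->	-1000	1000	transport	1	1
EX_asn	asn_e <->	-1000	1000	transport	1	1
EX_asp	asp_e <->	-1000	1000	transport	1	1
EX_glu	glu_e <->	-1000	1000	transport	1	1
EX_ser	ser_e <->	-1000	1000	transport	1	1
EX_ile	ile_e <->	-1000	1000	transport	1	1
EX_leu	leu_e <->	-1000	1000	transport	1	1
EX_o2	o2_e <->	-1000	1000	transport	1	0
EX_co2	co2_e <->	-1000	1000	transport	1	0
GLCt	glc_e -> glc	0	1000	transport	0	0
LACt	lac <-> lac_e	-1000	1000	transport	0	0
NH4t	nh4 -> nh4_e	0	1000	transport	0	0
ASNt	asn_e -> asn	0	1000	transport	0	0
ASPt	asp <-> asp_e	-1000	1000	transport	0	0
GLUt	glu <-> glu_e	-1000	1000	transport	0	0
SERt	ser_e -> ser	0	1000	transport	0	0
ILEt	ile_e -> ile	0	1000	transport	0	0
LEUt	leu_e -> leu	0	1000	transport	0	0
O2t	o2_e -> o2	0	1000	transport	0	0
CO2t	co2 -> co2_e	0	1000	transport	0	0
PYRtm	pyr -> pyr_m	0	1000	transport	0	0
HK	glc + atp -> g6p + adp	0	1000	glycolysis	0	0
GLYC	g6p + 3 adp + 2 nad_c -> 2 pyr + 3 atp + 2 nadh_c	0	1000	glycolysis	0	0
PPP	g6p + 2 nadp -> r5p + co2 + 2 nadph	0	1000	PPP	0	0
LDH	pyr + nadh_c <-> lac + nad_c	-1000	1000	glycolysis	0	0
NADHSH	nadh_c + fad -> nad_c + fadh2	0	1000	energy	0	0
PDH	pyr_m + nad_m -> accoa + co2 + nadh_m	0	1000	TCA	0	0
CS	accoa + oaa -> cit	0	1000	TCA	0	0
IDH	cit + nad_m -> akg + co2 + nadh_m	0	1000	TCA	0	0
AKGMAL	akg + nad_m + fad + adp -> mal + co2 + nadh_m + fadh2 + atp	0	1000	TCA	0	0
MDH	mal + nad_m <-> oaa + nadh_m	-1000	1000	TCA	0	0
PC	pyr_m + atp + co2 -> oaa + adp	0	1000	anaplerosis	0	0
ME	mal + nadp -> pyr_m + co2 + nadph	0	1000	anaplerosis	0	0
ASNASE	asn -> asp + nh4	0	1000	amino_acid	0	0
AST	asp + akg <-> oaa + glu	-1000	1000	amino_acid	0	0
GDH	glu + nad_m -> akg + nh4 + nadh_m	0	1000	amino_acid	0	0
SERD	ser -> pyr + nh4	0	1000	amino_acid	0	0
ILEDEG	ile + akg + 2 nad_m + fad -> glu + accoa + mal + 2 nadh_m + fadh2	0	1000	amino_acid	0	0
LEUDEG	leu + akg + nad_m + fad -> glu + 3 accoa + nadh_m + fadh2	0	1000	amino_acid	0	0
ETC_NADH	nadh_m + 0.5 o2 + 3 adp -> nad_m + 3 atp	0	1000	energy	0	0
ETC_FADH2	fadh2 + 0.5 o2 + 2 adp -> fad + 2 atp	0	1000	energy	0	0
ATPM	atp -> adp	0	1000	energy	0	0
BIOMASS	0.2 g6p + 0.1 r5p + 0.5 pyr + 0.3 accoa + 0.2 oaa + 0.2 akg + 0.15 asn + 0.2 asp + 0.25 glu + 0.2 ser + 0.1 ile + 0.15 leu + 35 atp + 0.5 nadph -> 35 adp + 0.5 nadp	0	1000	biomass	0	1
PROD_MAB	0.25 asn + 0.3 asp + 0.35 glu + 0.4 ser + 0.3 ile + 0.45 leu + 20 atp -> 20 adp	0	1000	product	0	1
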