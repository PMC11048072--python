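id	name	compartment	carbon	nitrogen
glc_e	D-glucose	extracellular	6	0
lac_e	L-lactate	extracellular	3	0
nh4_e	ammonium	extracellular	0	1
asn_e	L-asparagine	extracellular	4	2
asp_e	L-aspartate	extracellular	4	1
glu_e	L-glutamate	extracellular	5	1
ser_e	L-serine	extracellular	3	1
ile_e	L-isoleucine	extracellular	6	1
leu_e	L-leucine	extracellular	6	1
o2_e	oxygen	extracellular	0	0
co2_e	carbon dioxide	extracellular	1	0
glc	D-glucose	cytosol	6	0
g6p	glucose 6-phosphate	cytosol	6	0
r5p	ribose 5-phosphate	cytosol	5	0
pyr	pyruvate	cytosol	3	0
lac	L-lactate	cytosol	3	0
asn	L-asparagine	cytosol	4	2
asp	L-aspartate	cytosol	4	1
glu	L-glutamate	cytosol	5	1
ser	L-serine	cytosol	3	1
ile	L-isoleucine	cytosol	6	1
leu	L-leucine	cytosol	6	1
nh4	ammonium	cytosol	0	1
nadh_c	NADH (cytosolic)	cytosol	0	0
nad_c	NAD+ (cytosolic)	cytosol	0	0
nadph	NADPH	cytosol	0	0
nadp	NADP+	cytosol	0	0
atp	ATP	cytosol	0	0
adp	ADP	cytosol	0	0
pyr_m	pyruvate	mitochondrion	3	0
accoa	acetyl group of acetyl-CoA	mitochondrion	2	0
cit	citrate	mitochondrion	6	0
akg	2-oxoglutarate	mitochondrion	5	0
mal	L-malate	mitochondrion	4	0
oaa	oxaloacetate	mitochondrion	4	0
o2	oxygen	mitochondrion	0	0
co2	carbon dioxide	mitochondrion	1	0
nadh_m	NADH (mitochondrial)	mitochondrion	0	0
nad_m	NAD+ (mitochondrial)	mitochondrion	0	0
fadh2	FADH2	mitochondrion	0	0
fad	FAD	mitochondrion	0	0
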