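# Curated stoichiometric network of ectoine synthesis, degradation and cycling
# in Halomonas elongata.  Glycolysis is lumped to one ATP-neutral reaction to
# PEP; NADH and NADPH are one interconvertible couple; acetate re-ligation is
# lumped to 2 ATP per acetate (AMP-forming ligase + pyrophosphatase + adenylate
# kinase); NADH carries no ATP value (substrate-level accounting only).
# Species suffixed _e are environment pools.  ECTD, NADHOX and EX_ASP ship
# disabled (bounds 0 0).
# METABOLITES
# id	name	C	N	external
glc	D-glucose	6	0	0
pep	phosphoenolpyruvate	3	0	0
pyr	pyruvate	3	0	0
accoa	acetyl-CoA	23	7	0
coa	coenzyme A	21	7	0
co2	carbon dioxide	1	0	0
o2	molecular oxygen	0	0	0
mal	(S)-malate	4	0	0
oaa	oxaloacetate	4	0	0
asp	L-aspartate	4	1	0
asp4p	L-aspartyl-4-phosphate	4	1	0
aspsa	L-aspartate-4-semialdehyde	4	1	0
akg	2-oxoglutarate	5	0	0
glu	L-glutamate	5	1	0
gln	L-glutamine	5	2	0
nh3	ammonia	0	1	0
daba	L-2,4-diaminobutyrate	4	2	0
ngadaba	N-gamma-acetyl-L-2,4-diaminobutyrate	6	2	0
naadaba	N-alpha-acetyl-L-2,4-diaminobutyrate	6	2	0
ect	ectoine	6	2	0
hect	5-hydroxyectoine	6	2	0
succ	succinate	4	0	0
ace	acetate	2	0	0
atp	ATP	10	5	0
adp	ADP	10	5	0
nad	NAD(P)+	21	7	0
nadh	NAD(P)H	21	7	0
glc_e	D-glucose (environment)	6	0	1
nh3_e	ammonia (environment)	0	1	1
ect_e	ectoine (environment)	6	2	1
ace_e	acetate (environment)	2	0	1
co2_e	carbon dioxide (environment)	1	0	1
o2_e	molecular oxygen (environment)	0	0	1
asp_e	L-aspartate (environment)	4	1	1
# REACTIONS
# id	equation	reversible	lb	ub	ec	gene
GLYC	glc + 2 nad -> 2 pep + 2 nadh	0	0	inf
PYK	pep + adp -> pyr + atp	0	0	inf	2.7.1.40
PDH	pyr + coa + nad -> accoa + co2 + nadh	0	0	inf	1.2.4.1
PPC	pep + co2 -> oaa	0	0	inf	4.1.1.31
MAE	pyr + co2 + nadh <-> mal + nad	1	-inf	inf	1.1.1.38
MDH	mal + nad <-> oaa + nadh	1	-inf	inf	1.1.1.37
AAT	oaa + glu <-> asp + akg	1	-inf	inf	2.6.1.1
ASK	asp + atp -> asp4p + adp	0	0	inf	2.7.2.4	Helo_3742
ASD	asp4p + nadh -> aspsa + nad	0	0	inf	1.2.1.11	Helo_1954
ECTB	aspsa + glu -> daba + akg	0	0	inf	2.6.1.76	Helo_2589
ECTA	daba + accoa -> ngadaba + coa	0	0	inf	2.3.1.178	Helo_2588
ECTC	ngadaba -> ect	0	0	inf	4.2.1.108	Helo_2590
ECTD	ect + akg + o2 -> hect + succ + co2	0	0	0	1.14.11.55	Helo_4008
DOEA	ect -> naadaba	0	0	inf	3.5.4.44	Helo_3665
DOEB	naadaba -> daba + ace	0	0	inf	3.5.1.125	Helo_3664
DOED	daba + akg <-> aspsa + glu	1	-inf	inf	2.6.1.76	Helo_3661
DOEC	aspsa + nad -> asp + nadh	0	0	inf	1.2.1.-	Helo_3662
ACS	ace + 2 atp + coa -> accoa + 2 adp	0	0	inf	6.2.1.1
GDH	akg + nh3 + nadh -> glu + nad	0	0	inf	1.4.1.2	Helo_3049
GS	glu + nh3 + atp -> gln + adp	0	0	inf	6.3.1.2
GOGAT	gln + akg + nadh -> 2 glu + nad	0	0	inf	1.4.1.13
ATPDRAIN	atp <-> adp	1	-inf	inf
NADHOX	nadh -> nad	0	0	0
EX_GLC	glc_e -> glc	0	0	inf
EX_NH3	nh3_e -> nh3	0	0	inf
EX_ECT	ect -> ect_e	0	0	inf
EX_ACE	ace -> ace_e	0	0	inf
EX_CO2	co2 <-> co2_e	1	-inf	inf
EX_O2	o2_e -> o2	0	0	inf
EX_ASP	asp -> asp_e	0	0	0
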