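# Synthetic fixture library: hand-checked drug-like SMILES for tests and simulations.
# Format: name<TAB>SMILES. Structures are textbook approximations, not authoritative records.
aspirin	CC(=O)Oc1ccccc1C(=O)O
paracetamol	CC(=O)Nc1ccc(O)cc1
ibuprofen	CC(C)Cc1ccc(cc1)C(C)C(=O)O
naproxen	COc1ccc2cc(ccc2c1)C(C)C(=O)O
caffeine	Cn1cnc2c1c(=O)n(C)c(=O)n2C
nicotine	CN1CCCC1c1cccnc1
ethanol	CCO
benzene	c1ccccc1
toluene	Cc1ccccc1
phenol	Oc1ccccc1
aniline	Nc1ccccc1
pyridine	c1ccncc1
imidazole	c1cnc[nH]1
indole	c1ccc2[nH]ccc2c1
quinoline	c1ccc2ncccc2c1
naphthalene	c1ccc2ccccc2c1
morphine	CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
codeine	COc1ccc2CC3C4C=CC(O)C5Oc1c2C34CCN5C
atropine	CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1
cocaine	COC(=O)C1C(OC(=O)c2ccccc2)CC3CCC1N3C
quinine	COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1
warfarin	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
diazepam	CN1c2ccc(Cl)cc2C(=Nc3ccccc3)CC1=O
ketamine	CNC1(c2ccccc2Cl)CCCCC1=O
fluoxetine	CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1
sertraline	CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc12
imipramine	CN(C)CCCN1c2ccccc2CCc2ccccc21
amitriptyline	CN(C)CCC=C1c2ccccc2CCc2ccccc21
haloperidol	OC1(CCN(CCCC(=O)c2ccc(F)cc2)CC1)c1ccc(Cl)cc1
chlorpromazine	CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
metformin	CN(C)C(=N)NC(=N)N
glibenclamide	COc1ccc(Cl)cc1C(=O)NCCc1ccc(cc1)S(=O)(=O)NC(=O)NC1CCCCC1
atorvastatin	CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O
simvastatin	CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12
lovastatin	CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12
propranolol	CC(C)NCC(O)COc1cccc2ccccc12
atenolol	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
metoprolol	COCCc1ccc(OCC(O)CNC(C)C)cc1
salbutamol	CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
verapamil	COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC
nifedipine	COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]
amlodipine	CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl
diltiazem	CN(C)CCN1c2ccccc2SC(c2ccc(OC)cc2)C(OC(C)=O)C1=O
captopril	CC(CS)C(=O)N1CCCC1C(=O)O
enalapril	CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O
lisinopril	NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O
losartan	CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1
valsartan	CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(C)C)C(=O)O
furosemide	NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
hydrochlorothiazide	NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
spironolactone	CC(=O)SC1CCC2(C)C(CCC3(C)C2CCC23CCC(=O)O2)C1
digoxin	CC1OC(OC2CC(O)C(OC3CC(O)C(OC4CCC5(C)C(CCC6C5CC(O)C5(C)C(C7=CC(=O)OC7)CCC65O)C4)C(C)O3)C(C)O2)CC(O)C1O
penicillin	CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O
amoxicillin	CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O
cephalexin	CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1
ciprofloxacin	OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
norfloxacin	CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21
ofloxacin	CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23
erythromycin	CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)C(=O)C(C)C(O)C1(C)O
azithromycin	CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)CN(C)C(C)C(O)C1(C)C
tetracycline	CN(C)C1C2CC3C(=C(O)c4c(O)cccc4C3(C)O)C(=O)C2=C(O)C1(O)C(N)=O
doxycycline	CN(C)C1C2C(O)C3C(=C(O)c4c(O)cccc43)C(=O)C2=C(O)C1(O)C(N)=O
chloramphenicol	OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]
metronidazole	Cc1ncc(n1CCO)[N+](=O)[O-]
trimethoprim	COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC
sulfamethoxazole	Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1
isoniazid	NNC(=O)c1ccncc1
rifampicin-frag	Cc1cc2cc(O)c(C)c(O)c2c(O)c1O
ethambutol	CCC(CO)NCCNC(CC)CO
fluconazole	OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F
ketoconazole	CC(=O)N1CCN(CC1)c1ccc(OCC2COC(Cn3ccnc3)(O2)c2ccc(Cl)cc2Cl)cc1
acyclovir	Nc1nc2n(COCCO)cnc2c(=O)[nH]1
zidovudine	Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O
lamivudine	Nc1ccn(C2CSC(CO)O2)c(=O)n1
oseltamivir	CCOC(=O)C1=CC(OC(CC)CC)C(NC(C)=O)C(N)C1
methotrexate	CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)NC(CCC(=O)O)C(=O)O
fluorouracil	O=c1[nH]cc(F)c(=O)[nH]1
mercaptopurine	Sc1ncnc2[nH]cnc12
cytarabine	Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1
gemcitabine	Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1
imatinib	Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1
gefitinib	COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1
erlotinib	COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC
sorafenib	CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(c3)C(F)(F)F)cc2)ccn1
tamoxifen	CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1
raloxifene	Oc1ccc2sc(-c3ccc(O)cc3)c(C(=O)c3ccc(OCCN4CCCCC4)cc3)c2c1
dexamethasone	CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO
prednisolone	CC12CC(O)C3C(CCC4=CC(=O)C=CC34C)C1CCC2(O)C(=O)CO
hydrocortisone	CC12CC(O)C3C(CCC4=CC(=O)CCC34C)C1CCC2(O)C(=O)CO
testosterone	CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O
estradiol	CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
progesterone	CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C
cholesterol	CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C
quercetin	Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O
resveratrol	Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1
curcumin	COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O
genistein	Oc1ccc(-c2coc3cc(O)cc(O)c3c2=O)cc1
berberine	COc1ccc2cc3[n+](cc2c1OC)CCc1cc2c(cc1-3)OCO2
capsaicin	COc1cc(CNC(=O)CCCCC=CC(C)C)ccc1O
menthol	CC(C)C1CCC(C)CC1O
camphor	CC1(C)C2CCC1(C)C(=O)C2
limonene	CC(=C)C1CCC(C)=CC1
vanillin	COc1cc(C=O)ccc1O
salicylic-acid	OC(=O)c1ccccc1O
benzoic-acid	OC(=O)c1ccccc1
citric-acid	OC(=O)CC(O)(CC(=O)O)C(=O)O
glucose	OCC1OC(O)C(O)C(O)C1O
sucrose	OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O
urea	NC(N)=O
glycine	NCC(=O)O
tryptophan	NC(Cc1c[nH]c2ccccc12)C(=O)O
tyrosine	NC(Cc1ccc(O)cc1)C(=O)O
phenylalanine	NC(Cc1ccccc1)C(=O)O
histamine	NCCc1c[nH]cn1
serotonin	NCCc1c[nH]c2ccc(O)cc12
dopamine	NCCc1ccc(O)c(O)c1
epinephrine	CNCC(O)c1ccc(O)c(O)c1
melatonin	COc1ccc2[nH]cc(CCNC(C)=O)c2c1
ranitidine	CNC(=CN(=O)=O)NCCSCc1ccc(CN(C)C)o1
cimetidine	CC1=C(CSCCNC(=NC)NC#N)N=CN1
omeprazole	COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
loratadine	CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1
cetirizine	OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1
diphenhydramine	CN(C)CCOC(c1ccccc1)c1ccccc1
montelukast	CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(C=Cc2ccc3ccc(Cl)cc3n2)c1
theophylline	Cn1c(=O)c2[nH]cnc2n(C)c1=O
allopurinol	O=c1[nH]cnc2[nH]ncc12
colchicine	COC1=CC(=O)C=C2CCC3(NC(C)=O)c4cc(OC)c(OC)c(OC)c4C(=C1)C23
pirfenidone	Cc1ccc(=O)n(-c2ccccc2)c1
nintedanib-frag	COC(=O)c1ccc2c(c1)NC(=O)C2=C(Nc1ccc(N(C)C(=O)CN2CCN(C)CC2)cc1)c1ccccc1
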