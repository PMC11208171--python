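position	mutation	freq_before	freq_adapted	freq_10th	aa_change	gene	annotation
925621	A->T		66.8	78.9	K21I (AAA->ATA)	fdhC	formate/nitrite transporter FdhC
950586	G->C	36.5	100	100	R165P (CGG->CCG)	hycB2	hydrogenase Fe-S subunit HycB2
1004414	G->A		44.9	33.1	P84S (CCG->TCG)	lctA	regulator for LDH/ETF complex
1004442	del15bp			6.2	coding (208-222/711 nt)	lctA	regulator for LDH/ETF complex
1004462	C->T			12.8	G68S (GGT->AGT)	lctA	regulator for LDH/ETF complex
1243519	C->T			5.3	P236L (CCT->CTT)	acsA	CO dehydrogenase, catalytic subunit AcsA
1245411	T->A			10.1	I225N (ATC->AAC)	cooC2	CO dehydrogenase nickel-insertion accessory protein CooC2
1245718	C->T			8.7	P47L (CCT->CTT)	acsB1	acetyl CoA synthase catalytic subunit AcsB
1245999	G->A			21.8	V141I (GTA->ATA)	acsB1	acetyl CoA synthase catalytic subunit AcsB
2849933	A->T			34.9	intergenic (-79/+265)	nifJ/Awo_c24340	pyruvate:ferredoxin oxidoreductase NifJ/hypothetical protein
2884514	G->A		44.6	39.3	L264F (CTT->TTT)	fliG	flagellar motor switch protein FliG
2884844	G->A		30.1	42.3	R154W (CGG->TGG)	fliG	flagellar motor switch protein FliG
2939053	(ATGGCTCTTT)x1->x2			8.3	coding (959/1014 nt)	fliM	flagellar motor switch protein FliM
2940413	G->A			13.1	P126L (CCA->CTA)	motB	flagellar motor protein MotB
3227278	A->C		76.4	81.2	I29S (ATT->AGT)	modC2	molybdate/tungsten ABC transport system ATP binding protein ModC2
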