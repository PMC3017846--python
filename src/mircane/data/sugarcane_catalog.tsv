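family	source	source_id	gene	mature_sequence	mature_sequence_alt	arm	nm	precursor_len	mfei	conserved_in_rice
miR156	EST	TC110664	SsMIR156b/c	UGACAGAAGAGAGUGAGCAC		5p	0	411	0.81	yes
miR159	EST	TC79108	SsMIR159	UUUGGAUUGAAGGGAGCUCUG		3p	0	265	0.78	yes
miR167	EST	TC105794	SsMIR167	UGAAGCUGCCAGCAUGAUCUG		5p	0	193	0.93	yes
miR168	EST	TC97302	SsMIR168	UCGCUUGGUGCAGAUCGGGAC		5p	0	104	0.86	yes
miR169	EST	TC105581	SsMIR169	UAGCCAAGGAUGACUUGCCGG		5p	0	148	0.92	yes
miR396	EST	CA240723	SsMIR396	UUCCACAGCUUUCUUGAACUG		5p	0	134	1.02	yes
miR827	EST	CA215078	SsMIR827	UUAGAUGACCAUCAGCAAACA		3p	0	140	1.01	yes
miR408	EST	TC108481	SsMIR408a	CUGCACUGCCUCUUCCCUGGC		3p	0	215	0.67	yes
miR408	EST	TC74315	SsMIR408b	CUGCACUGCCUCUUCCCUGGC		3p	0	283	0.80	yes
miR437	EST	CA185316	SsMIR437a	AAAGUUAGAGAAGUUUGACUU		3p	0	195	1.36	yes
miR437	EST	CA191146	SsMIR437b	AAAGUUAGACAAGUUUGACAU		3p	2	233	0.92	yes
miR437	EST	CA300436	SsMIR437c	AAAGUUAGAGAAGUCUGACUU		3p	1	197	1.36	yes
miR444	EST	CA186150	SsMIR444a	UGCAGUUGUUGCCUCAAGCUU		3p	0	105	1.31	yes
miR444	EST	CA105916	SsMIR444b	UGCAGUUGUUGCCUCAAGCUU	UUGUGGCUUUCUUGCAAGUUG	3p	0	132	1.24	yes
miR444	EST	TC110432	SsMIR444c	UGCAGUUGUUGUCUCAAGCUU	UGUUGUCUCAAGCUUGCUGCC	3p	0	152	1.20	yes
miR528	EST	CA290495	SsMIR528	UGGAAGGGGCAUGCAGAGGAG		5p	0	94	0.86	yes
miR1128	EST	CA222833	SsMIR1128	UACUACUCCCUCCGUCCCAAA		5p	1	275	1.17	no
miR1432	BAC	FJ348731	SsMIR1432	CUCAGGAAAGAUGACACCGAC		5p	1	118	1.15	yes
miR319	EST	TC87836	SsMIR319	UUGGACUGAAGGGUGCUCCC		3p	0	n.d.	n.d.	yes
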