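accession	name	score	sequence	start	average_log2_ratio
YLL026W	HSP104	65	MNDQT	1	-8.7
YPL111W	CAR1	66	METGP	1	-7.3
YDL029W	ARP2	54	MDPHN	1	-6.5
YGR078C	PAC10	47	MDTLF	1	-6.0
YJL136C	RPS21B	88	MENDK	1	-5.6
YER133W	GLC7	74	MDSQP	1	-4.7
YGR180C	RNR4	44	MEAHN	1	-4.5
YPR181C	SEC23	51	MDFET	1	-4.3
YLR078C	BOS1	51	MNALY	1	-3.0
YOR045W	TOM6	117	MDGMF	1	-2.4
YOR027W	STI1	42	MDDIN	198	-0.7
YER055C	HIS1	55	MDLVN	1	-6.9
YCL001W	RER1	97	MDYDS	1	-5.5
YDL100C	GET3	39	MDLTV	1	-4.8
YKR057W	RPS21A	96	MENDK	1	-4.4
YDR394W	RPT3	43	MEELG	1	-3.8
YBL082C	ALG3	67	MEGEQ	1	-3.1
YDR470C	UGO1	89	MNNNN	1	-2.7
YBR143C	SUP45	40	MDNEV	1	-9.6
YNL189W	SRP1	67	MDNGT	1	-8.0
YLR264W	RPS28B	32	MDSKT	1	-8.0
YLR438C-A	LSM3	40	METPL	1	-7.5
YHR028C	DAP2	69	MEGGE	1	-7.4
YLR118C		48	MNGLR	1	-7.1
YMR074C		60	MDPEL	1	-6.9
YGR275W	RTT102	30	MDPQT	1	-6.3
YFL038C	YPT1	40	MNSEY	1	-6.2
YIL076W	SEC28	33	MDYFN	1	-5.9
YNL313C		45	METLL	1	-5.8
YOL129W	VPS68	58	MEADD	1	-5.3
YJL041W	NSP1	42	MNFNT	1	-5.3
YOL086W-A		34	MNDDE	1	-5.1
YIL088C	AVT7	46	MEATS	1	-4.6
YPL262W	FUM1	41	MNSSF	24	-4.5
YLR178C	TFS1	54	MNQAI	1	-4.3
YFL023W	BUD27	67	MDLLA	1	-4.0
YHR060W	VMA22	53	MDTTD	10	-3.7
YLR423C	ATG17	30	MNEAD	1	-3.7
YGR231C	PHB2	34	MNRSP	1	-3.6
YLR430W	SEN1	54	MNSNN	1	-3.5
YLR119W	SRN2	36	MDVVP	31	-3.5
YNL044W	YIP3	51	MNQLG	1	-3.5
YPR021C	AGC1	43	MEQIN	1	-3.4
YDL116W	NUP84	48	MELSP	1	-3.0
YDR017C	KCS1	39	MDTSH	1	-2.9
YJR089W	BIR1	35	MDGQI	1	-2.9
YDL188C	PPH22	34	MDMEI	1	-2.8
YCR002C	CDC10	70	MDPLS	1	-2.6
YDR129C	SAC6	32	MNIVK	1	-2.5
YDL128W	VCX1	79	MDATT	1	-2.5
YNL092W		50	MDENE	1	-2.1
YGL242C		61	MNTEG	1	-1.9
YLR056W	ERG3	66	MDLVL	1	-1.8
YER012W	PRE1	44	MDIIL	1	-1.6
YEL056W	HAT2	47	MENQE	1	-1.5
YDR320C-A	DAD4	50	MENPH	1	-1.2
YDL141W	BPL1	39	MNVLV	1	-1.1
YBR154C	RPB5	32	MDQEN	1	-0.3
YDL122W	UBP1	31	MDLFI	1	-0.2
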