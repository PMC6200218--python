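family	superfamily	consensus_len_bp	tsd_pattern	copies_Taestivum	copies_Tturgidum	copies_Aetauschii	copies_Turartu	notes
Thalos	Stowaway	158	TA	42321	27946	12557	5249
Athos	Stowaway	81	TA	19359	10637	5297	2314
Pan	Stowaway	123	TA	14296	11108	3838	1407
Icarus	Stowaway	108	TA	6795	4512	1649	694
Hades	Stowaway	92	TA	3656	2635	898	643
Eos	Stowaway	344	TC	3264	2150	974	465
Xados	Stowaway	112	AG	1937	1425	445	344
Minos	Stowaway	236	TA	1253	1022	164	636
Aison	Stowaway	215	TA	852	692	115	166
Stolos	Stowaway	255	TA	720	509	197	232
Fortuna	Stowaway	349	TA	509	440	35	112
Oleus	Stowaway	146	TA	407	258	130	106
Antonio	Stowaway	104	TA	320	226	84	84
Minimus	Stowaway	51	TA	320	206	86	76
Tantalos	Stowaway	253	CC	105	73	31	28
Phoebus	Stowaway	319	CG	34	26	7	3
Polyphemus	Stowaway	237	TC	22	11	8	1
Jason	Stowaway	256	TA	18	10	7	4
Orpheus	Tourist	272	TAA	1912	1474	299	546
Kerberos	Tourist	285	TA	1594	808	689	100
Coeus	Tourist	273	TTA	777	612	53	163
Xenon	Tourist	305	AG	556	422	122	221
Victor	Tourist	276	GCA	194	106	57	45
Gerald	Mutator	345	AAAAATTAA	1119	925	191	401
Rhea	Mutator	561	TACAAAAAA	473	346	124	194
Spring	Mutator	223	GGGGAACC	319	270	40	17
Argus	Mutator	327	TTTAATTAA	306	280	6	10
Vacuna	Mutator	464	TTT	197	141	29	40
Gabriel	Mutator	407	CCTC	16	14	5	7
Belus	Unknown	173	CATG	8522	6114	2014	929
Keres	Unknown	71	CGGTCCG	640	510	93	100
Gorgon	Unknown	56	GC	217	123	64	53
Inbar	Unknown	58	TA	1911	1846	24	93	consensus length also reported as 68 bp in prose
Remus	Mutator	829	CG	211	213	7	27
Marius	Stowaway	691	TA	15	11	3	3
Murray	Mutator	937	TACTGCTCC	2	1	0	0
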