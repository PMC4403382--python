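# Bundled minimal gene model: approximate hg19 spans (0-based half-open)
# for the recurrently altered genes used by the default profiles. Not a
# full annotation; supply a BED for other gene sets.
1	27022522	27108601	ARID1A
1	120454176	120612240	NOTCH2
1	152274651	152297679	FLG
1	209958968	209979520	IRF6
2	47630206	47710367	MSH2
2	48010221	48034092	MSH6
3	10068098	10143614	FANCD2
3	30647994	30735634	TGFBR2
3	37034841	37107380	MLH1
3	41240942	41281939	CTNNB1
3	52579368	52719933	PBRM1
3	178866311	178952497	PIK3CA
6	136578001	136611025	BCLAF1
6	157099063	157531913	ARID1B
7	42000547	42277469	GLI3
7	140419127	140624564	BRAF
8	128747680	128753674	MYC
9	2015342	2193624	SMARCA2
9	21967751	21995300	CDKN2A
9	22002902	22009280	CDKN2B
9	35073832	35080013	FANCG
9	97861336	98079991	FANCC
9	101867487	101916474	TGFBR1
9	139388896	139440238	NOTCH1
11	22646888	22647387	FANCF
11	69455855	69469242	CCND1
11	108093211	108239829	ATM
12	25358180	25403854	KRAS
12	46123448	46301823	ARID2
12	52345451	52390862	ACVR1B
12	58141510	58149796	CDK4
13	32889611	32973805	BRCA2
13	48877887	49056122	RB1
16	337440	402673	AXIN1
16	89803957	89883065	FANCA
17	7571720	7590868	TP53
17	41196312	41277500	BRCA1
17	56431038	56494956	RNF43
18	48556583	48611411	SMAD4
19	1205798	1228431	STK11
19	11071598	11176071	SMARCA4
20	57414773	57486250	GNAS
22	29083731	29137822	CHEK2
X	47004573	47046214	RBM10
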