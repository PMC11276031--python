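amino_acid	codon	count_A_capillus_veneris	count_C_richardii	count_D_complanatum	count_S_moellendorffii	rscu_A_capillus_veneris	rscu_C_richardii	rscu_D_complanatum	rscu_S_moellendorffii
Ala	GCA	328432	989237	1115071	214300	1.466	1.618	1.578	0.871
Ala	GCC	173863	376265	438127	244188	0.776	0.615	0.62	0.993
Ala	GCG	91978	216035	220899	248354	0.411	0.353	0.313	1.01
Ala	GCU	301610	864565	1051993	277044	1.347	1.414	1.489	1.126
Cys	UGC	119373	318043	311419	145304	1.022	0.89	0.922	1.325
Cys	UGU	114153	396826	364193	73974	0.978	1.11	1.078	0.675
Asp	GAC	200175	514792	569822	311951	0.691	0.573	0.599	1.012
Asp	GAU	378798	1281555	1331887	304291	1.309	1.427	1.401	0.988
Glu	GAA	328776	1157275	1341654	272737	0.911	1.043	1.089	0.721
Glu	GAG	393172	1061377	1123251	483614	1.089	0.957	0.911	1.279
Phe	UUC	173387	536715	507514	268206	0.794	0.814	0.716	1.129
Phe	UUU	263340	782464	910388	206909	1.206	1.186	1.284	0.871
Gly	GGA	213205	714541	837986	250272	1.135	1.317	1.386	1.256
Gly	GGC	182091	422746	489520	242831	0.97	0.779	0.81	1.219
Gly	GGG	155260	404290	427736	157826	0.827	0.745	0.708	0.792
Gly	GGU	200691	629334	662767	145882	1.069	1.16	1.096	0.732
His	CAC	108927	272492	306282	165967	0.712	0.594	0.648	1.189
His	CAU	197221	645662	639124	113122	1.288	1.406	1.352	0.811
Ile	AUA	132939	495964	476885	89876	0.763	0.854	0.788	0.493
Ile	AUC	155759	472970	492669	282736	0.894	0.815	0.814	1.55
Ile	AUU	233749	772433	845577	174532	1.342	1.331	1.398	0.957
Lys	AAA	264644	906517	1046153	208904	0.853	0.954	0.998	0.663
Lys	AAG	356189	994699	1049801	421403	1.147	1.046	1.002	1.337
Leu	CUA	114756	342395	398912	92206	0.616	0.644	0.688	0.409
Leu	CUC	168150	414007	386053	331224	0.903	0.778	0.666	1.47
Leu	CUG	182510	514216	600222	277257	0.98	0.967	1.036	1.231
Leu	CUU	279707	857324	932495	200373	1.502	1.612	1.609	0.889
Leu	UUA	123649	451252	468975	60664	0.629	0.745	0.698	0.44
Leu	UUG	269356	759794	874982	215282	1.371	1.255	1.302	1.56
Met	AUG	282681	866305	860493	276469	1	1	1	1
Asn	AAC	163371	483812	520991	238044	0.772	0.696	0.707	1.195
Asn	AAU	259882	906830	953288	160282	1.228	1.304	1.293	0.805
Pro	CCA	184259	582251	663628	178328	1.322	1.494	1.505	1.253
Pro	CCC	109951	234875	252967	115033	0.789	0.603	0.574	0.808
Pro	CCG	61060	153096	151889	144537	0.438	0.393	0.344	1.016
Pro	CCU	202036	588760	695197	131240	1.45	1.511	1.577	0.922
Gln	CAA	247609	716536	854813	184836	1.049	1.027	1.043	0.822
Gln	CAG	224626	678388	783813	264729	0.951	0.973	0.957	1.178
Arg	AGA	163721	556336	601738	137503	1.033	1.098	1.152	0.924
Arg	AGG	153253	456708	443328	160121	0.967	0.902	0.848	1.076
Arg	CGA	82637	238749	295095	107147	1.102	1.157	1.236	1.062
Arg	CGC	79522	167607	190657	116118	1.06	0.813	0.798	1.151
Arg	CGG	65558	173829	182712	111949	0.874	0.843	0.765	1.11
Arg	CGU	72345	244908	286909	68380	0.964	1.187	1.201	0.678
Ser	AGC	179597	440360	505404	236996	1.054	0.901	0.924	1.39
Ser	AGU	161155	537111	588387	104037	0.946	1.099	1.076	0.61
Ser	UCA	205493	738956	786199	102542	1.252	1.407	1.409	0.671
Ser	UCC	136411	378592	385704	178370	0.831	0.721	0.691	1.168
Ser	UCG	78268	211624	222177	185204	0.477	0.403	0.398	1.213
Ser	UCU	236121	772144	837411	144767	1.439	1.47	1.501	0.948
Thr	ACA	205060	670959	703525	127562	1.495	1.624	1.551	0.914
Thr	ACC	115165	265042	305155	131863	0.839	0.642	0.673	0.944
Thr	ACG	66861	184439	189383	154925	0.487	0.446	0.418	1.11
Thr	ACU	161738	532033	615793	144121	1.179	1.288	1.358	1.032
Val	GUA	128256	433311	448957	82007	0.692	0.802	0.751	0.404
Val	GUC	137417	379589	378766	211259	0.742	0.702	0.633	1.041
Val	GUG	250181	619010	715051	312706	1.35	1.145	1.196	1.54
Val	GUU	225220	729989	848969	206157	1.216	1.351	1.42	1.015
Trp	UGG	148751	416101	457356	168797	1	1	1	1
Tyr	UAC	119310	326033	350895	192562	0.828	0.711	0.744	1.247
Tyr	UAU	168731	591712	592105	116394	1.172	1.289	1.256	0.753
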