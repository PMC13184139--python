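subject_id	region_001	region_002	region_003	region_004	region_005	region_006	region_007	region_008
S000	1.821266902362302	2.26690672922697	1.093374085239730	 0.5598238129470214	1.268451019252125	0.986433308427421	1.091079157071454	 0.0864640139417223
S001	0.853836126157198	1.69340029928087	1.372770864491839	 0.3312762543062077	0.721856458112152	1.123554299549829	1.295801377121931	 0.6625962901778093
S002	1.283830957688963	1.62892356501273	1.097589473971015	 0.2347523925422963	1.018207944566631	1.502463142076029	1.105531820201297	 0.4904814293102413
S003	1.457784281661366	1.59077600827734	1.038971497232863	 0.5137512049933410	1.049578805983274	1.121379872413866	1.176115306288157	 0.1014410392951398
S004	1.419920185833980	2.01067637991749	0.715584745280302	 0.9770130205414138	0.907235831360797	1.515895000856812	0.968752583825444	 0.6525379557155904
S005	1.703787491326482	2.24057714667965	1.081247940263372	 0.2660829728257625	1.160478372786140	1.166182779172721	1.060704163559317	 0.2606267641083216
S006	1.052308282762715	1.93459614622504	0.523875629657065	 0.2576446161876419	1.197099235695229	1.772155733785073	0.915418346448298	 0.5822599246442595
S007	1.492417224164926	1.67930833913126	0.985484168595003	 0.5872376186116213	1.360766212402619	1.141853647403544	0.983834172874050	 0.4514182165432319
S008	1.949917312183881	2.90657016010483	0.371799462035047	 0.7160161582422608	1.767939999680327	1.239746045121904	1.131712828700133	-0.5717134752938662
S009	1.663447952213670	2.13757878366624	0.612384316537276	 0.5091657040245983	1.395967232498272	1.468712293385000	1.177519702076815	-0.1188660384157167
S010	1.182429174891308	1.96685425449542	1.010595745773112	 0.2606352271918257	1.230611978431911	1.230417464616756	1.176650517977698	 0.0973482040690757
S011	1.411894317432781	1.84754469610359	0.949887992402958	 0.5944955769755303	1.031543237057403	1.359157114478676	1.209141106394009	-0.0207658561498590
S012	1.764648209502908	1.97367991598268	0.903920897669187	 0.2387576712862016	1.141199772463548	1.098448513920637	1.240383876323454	 0.4978300863053882
S013	1.329736589792897	2.29218860816591	0.977455711906108	 0.5678275555359299	1.423829159218772	1.258347682247899	1.493192162764704	 0.0104112293523276
S014	1.178290279009067	2.28851881067974	0.834112332139569	 0.3485777268861157	1.312833188682142	1.011776610184536	1.613798222186071	-0.2901247320557451
S015	1.313176873700636	1.98063883368699	0.498919125071412	 0.7746583175161309	1.380195932439165	1.852306131246955	1.267888667765691	-0.4427191938553146
S016	1.243007340409651	1.86208059160571	0.940299220009580	 0.4709646447829162	1.299521183738665	0.800985651045264	0.908497355701800	 0.4688835147336894
S017	1.728100613306887	2.03584050308582	1.235220789142886	 0.1231011541226369	1.531157523416842	1.667033517463075	1.559966359163047	 0.1775209045269910
S018	1.482033855199290	2.05854190868478	0.769033361027060	 0.4461808099679591	1.401629918980549	1.394450770330195	1.470863617463608	-0.2809426953434313
S019	1.940336729768403	2.55879367042193	0.340705099069003	 0.5788648259441735	1.551762295990836	1.594168288502039	0.915383447141424	-0.1011408344393866
S020	1.613407513522377	2.49254328581123	0.597880885564936	 0.2601332112971790	1.393685570420701	1.929829844180452	1.008216234460691	-0.1657183752300742
S021	1.546912409814561	2.38630899078078	0.655247164685668	-0.1558028649404199	1.400231915848311	1.589772787733299	1.415279068568374	-0.3730109627302227
S022	1.382497245968412	2.49134805021683	0.385955297033088	 0.1512870665585176	1.342129981562334	1.692373415453706	1.136270671876381	-0.4157072556500210
S023	1.003679041899430	2.54381568286189	0.601610083538881	 0.2551088523232631	1.004188322867579	1.642743390029847	0.993533878677530	 0.0949077092391703
S024	1.804218193438189	1.98658972335843	0.812860644629590	 0.1959882648680240	1.462154284660778	1.491236897215328	1.742816503026868	-0.0994812628839052
S025	1.823859223922388	1.75520220513291	1.252322262002626	 0.8269324025165268	0.997662828664449	0.845614460138884	1.043689579640306	 0.1350586760897847
S026	1.836040426461187	2.45141725199364	0.782073742208808	 0.2400367857714116	1.354894709204243	1.746588222145857	1.287782558740800	-0.3137757993504258
S027	1.386688336287045	1.74011844644814	1.008525229476674	 0.3934047918460158	1.133261321119982	1.223428168516883	0.916617113727281	 0.5684162847031042
S028	1.424037624253660	1.43657041075547	1.161334656404136	-0.2122847582332799	1.304703006034609	1.376449944117819	1.419217198897861	 0.9820261107426572
S029	1.115593845535936	1.98737045659620	1.191178613538705	 0.3107737583869298	1.245015202367246	0.972525340016867	1.044200151013913	 0.5329468208508654
S030	1.294178385319848	2.08030980353252	0.986114869115430	 0.8928802101728068	1.228838830767506	1.002693277561553	1.083712173317985	 0.1702161416626982
S031	1.663346959673972	1.98296298100284	0.765924690371851	 0.5402276959745126	1.087147612058342	1.412745726646882	0.803576791495208	 0.4952395140736008
S032	1.826018224550391	2.04113861014450	0.330467175284569	 0.2336531320605981	0.885947508781247	1.107039408979314	1.175474946034552	-0.1530893744656666
S033	1.787565068152807	2.70579457876396	0.514668706856848	-0.1781712026393180	1.248235403588325	1.649911529071428	1.148984142079678	-0.0723423988633994
S034	1.231956552194465	2.02979879655693	0.717140306312794	-0.0657344350262825	1.240564044938856	1.412495898590701	0.870832050030755	-0.1895082379186457
S035	1.668035172585407	2.19145874759717	0.492256102267976	 0.5097555857586594	1.355151836839038	1.583433627957010	1.056962377304005	 0.3027667982338171
S036	1.805176482596270	2.50194052043878	0.409758463516907	-0.0825173698450599	1.691310268849308	1.663540648388342	0.882773138413705	-0.1403450474268388
S037	1.333344652105556	1.93276513512607	0.315179085884879	 0.4066896363969505	1.311046783095539	1.323875484579138	0.784573025602335	 0.3861730000654371
S038	1.606064912146842	2.69082822237188	1.262901395359054	 0.5367076773424350	1.258766018943936	1.682293315278883	1.579886219094334	-0.1774179150793621
S039	1.091303914400727	2.28248137388354	0.495406528335856	 0.7715496647747180	1.082215787543872	1.556441509392075	0.739639090680245	 0.5658572103946871
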