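subject_id	region_001	region_002	region_003	region_004	region_005	region_006	region_007	region_008
S000	1.95163897179	2.41220102768	0.870433021359	0.278500076937	1.67398286259	0.829950635518	1.05287497199	-0.354434199387
S001	0.589836128115	1.61357199361	1.5368608368	0.496837241366	0.772305002027	1.0940189123	1.3160157881	1.09781866355
S002	0.996899617146	1.58494692026	1.26028924171	0.407614011435	1.05079746	1.45472830445	1.15557982343	0.919466750927
S003	1.15314616665	1.52954006335	1.2012171009	0.639226750206	1.06794565149	1.09344762143	1.20889536579	0.562619464195
S004	1.55136765019	2.17120221575	0.493229036028	0.784475860343	1.27571516853	1.38861314958	0.958970577951	0.30307881359
S005	1.83469125631	2.39235559408	0.858359816324	-0.0641882575701	1.54316174698	1.01916712259	0.998845851962	-0.115213590158
S006	1.18464977504	2.09541466077	0.300490713593	-0.0836678947859	1.60128543229	1.67807463878	0.905732517718	0.206675790933
S007	1.62353237588	1.84072652975	0.761918686201	0.305161074735	1.7831722656	1.00955547964	0.94221632946	0.044178147198
S008	2.29609844576	2.92485387972	0.482175297631	1.04689804668	1.06841125679	1.54305292605	1.11702831745	-0.557199614717
S009	1.35442689322	2.06887660551	0.775213538355	0.61256651074	1.3949929548	1.4468952087	1.20275619163	0.331261104413
S010	0.902220132175	1.87659209644	1.17280079593	0.428704816965	1.24025633336	1.2011784643	1.22008994493	0.547087918355
S011	1.54356918033	2.01221726708	0.726321952603	0.329915513388	1.40075660428	1.23429076024	1.16923443385	-0.441985207033
S012	1.43787876201	1.85800597526	1.0653901861	0.422771525715	1.1482758238	1.07110602281	1.26603995943	0.940624945465
S013	1.46178381932	2.4459733341	0.754111840005	0.305001897229	1.82741572637	1.1145459212	1.48037326123	-0.379381066844
S014	0.906295345941	2.18674416433	0.995503835656	0.483813398991	1.32916488915	1.00698080508	1.63632825565	0.162101914844
S015	1.52276815709	1.66754967293	0.616948613236	1.10657761718	0.654597899216	2.14126191784	1.24346475535	-0.449367935017
S016	0.953490679055	1.76557229673	1.10199656296	0.604881514202	1.292033797	0.795530662849	0.964272419415	0.910794604399
S017	1.42341668543	1.98927528239	1.39898244704	0.295022919798	1.53503471818	1.62318388578	1.59793250021	0.593997831314
S018	1.6136037447	2.21829534562	0.544583268857	0.155590253253	1.8064680675	1.26949198718	1.46111817951	-0.728552166973
S019	2.07064574759	2.70749374019	0.116559265636	0.317895351872	1.9767538531	1.46330061258	0.875766686583	-0.524883220384
S020	1.74486272516	2.6504822456	0.375198288306	-0.0522345681203	1.7875828547	1.82326047461	0.957668055127	-0.552103449637
S021	1.67857284895	2.54850202435	0.432873393287	-0.550555184022	1.79340781466	1.44350482948	1.42051310376	-0.786982158393
S022	1.60009917192	2.33828855291	0.497679470089	0.472228486016	0.611172092926	1.98593534865	1.12465156256	-0.443684321093
S023	1.16916002764	2.51103875391	0.724115359307	0.576402463092	0.26214651577	1.9337237312	0.976139176542	0.0485902621002
S024	2.12849830263	1.77745058682	0.919449125244	0.516494639889	0.74440064726	1.78121679706	1.70315033371	-0.14207371066
S025	1.49562003122	1.67909693242	1.41580393016	0.884245724051	1.02494093626	0.83888627092	1.09119719538	0.590628831814
S026	2.1519635253	2.28615182631	0.917733865377	0.562559643015	0.625055434132	2.03880637822	1.2653240278	-0.35802701248
S027	1.66801781641	1.60388587238	1.12333207064	0.715053206937	0.412066630093	1.51369184747	0.909250804859	0.522071689774
S028	1.55532094628	1.6057111434	0.93866340327	-0.655869864787	1.72181018224	1.27130297058	1.44115932393	0.655219677539
S029	1.24783331348	2.14156359745	0.968730502859	-0.0214107626453	1.64886281698	0.815282787562	1.00073417414	0.158994823991
S030	1.42605047677	2.23421541169	0.762672849358	0.682884174165	1.62531935274	0.843440639143	1.0362192801	-0.24145526927
S031	2.00417387812	1.86270509014	0.895810352579	0.864974019337	0.364083247733	1.70486948841	0.781669457468	0.45890551767
S032	1.95658328127	2.20583209345	0.106242908789	-0.0990477299874	1.24176109813	0.923699813707	1.17741731843	-0.593473045996
S033	2.09769831885	2.64809775273	0.633778411904	0.136502370988	0.513030580271	1.9437934057	1.13367536572	-0.147556417414
S034	1.36393567056	2.19045592152	0.494808360189	-0.466650908898	1.64340277678	1.27208053488	0.844393423683	-0.665377105325
S035	1.35921955789	2.11764421106	0.654423289553	0.61206888551	1.35948478216	1.55427760832	1.09340118777	0.73021539245
S036	1.49254165512	2.40924931407	0.571589458553	0.131993024348	1.67128509228	1.63549832578	0.945295431759	0.297315356485
S037	1.03814707704	1.85548543152	0.476140144908	0.54803475915	1.3014657513	1.30147667983	0.824712247029	0.830294115703
S038	1.30404827721	2.53398183979	1.42668951439	0.63363570489	1.2800901001	1.63059689081	1.60455020521	0.269837368988
S039	0.817219170327	2.17570747147	0.657474501602	0.82933070825	1.10508799517	1.52299428658	0.792248032613	0.991349299293
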