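subject_id	site	age	sex
S000	2	31.2968795823	0
S001	1	22.0448652776	0
S002	1	36.724904756	0
S003	1	24.6882743314	0
S004	2	29.7270416634	1
S005	2	43.3770601832	0
S006	2	24.8930357718	1
S007	2	23.8333334838	0
S008	3	60.0818474634	1
S009	1	43.9572035839	1
S010	1	36.0662129975	0
S011	2	42.9294975054	0
S012	1	22.8686142448	0
S013	2	51.4070916551	0
S014	1	52.9693997626	0
S015	3	59.6967604116	1
S016	1	25.1761664629	0
S017	1	64.5583406344	0
S018	2	47.4856277754	0
S019	2	43.6159174326	1
S020	2	58.7643209011	1
S021	2	60.3000281334	1
S022	3	64.4473475138	1
S023	3	44.2147972392	1
S024	3	55.3668473476	0
S025	1	28.4893145468	0
S026	3	64.0147938131	1
S027	3	23.1157151733	0
S028	2	23.0378421091	0
S029	2	30.3928304165	0
S030	2	36.4488693229	0
S031	3	21.3861845396	1
S032	2	40.8950715945	1
S033	3	60.8218184962	1
S034	2	31.3834416453	1
S035	1	45.0735231691	1
S036	1	57.2068189674	1
S037	1	24.6257678592	1
S038	1	52.2022254448	0
S039	1	33.8581171786	1
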