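id	f0	f1	f2	f3	f4	f5	f6	f7	f8	f9	f10	f11	f12	f13	f14	f15	f16	f17	f18	f19	f20	f21	f22	f23	f24	f25	f26	f27	f28	f29	f30	f31
p0000	-1.581995	-0.950363	1.444313	0.871062	-0.389974	-0.948056	-1.84668	-0.401019	-0.157529	-0.065194	-0.168401	-1.186632	-0.098022	0.024956	1.27202	1.880283	-0.049591	-0.686604	-0.07015	-0.619697	-0.805477	-0.093373	-1.022037	0.625893	-0.098404	0.299748	-0.221558	-0.730058	-0.911397	-0.208069	-0.495213	0.253752
p0001	-1.521749	-0.959148	1.335709	0.738606	-0.372635	-0.872929	-1.878387	-0.478541	-0.049159	-0.114047	-0.137003	-1.23456	-0.083018	0.006192	1.309612	1.836686	-0.137733	-0.728466	-0.203003	-0.613848	-0.715274	-0.024544	-0.958268	0.662859	-0.088287	0.265107	-0.143593	-0.754221	-0.949969	-0.191964	-0.450888	0.225938
p0002	-1.508699	-0.967334	1.452999	0.819063	-0.3282	-0.918505	-1.903109	-0.403565	0.008422	-0.031791	-0.169264	-1.167566	-0.049431	-0.071608	1.214441	1.918657	-0.112291	-0.741647	-0.088754	-0.556174	-0.754432	-0.003828	-1.088888	0.5634	-0.093682	0.214892	-0.149167	-0.71425	-0.994108	-0.233633	-0.566324	0.279693
p0003	-0.036059	-1.384265	0.127683	-1.230931	-0.516527	-0.291192	-2.064331	0.16818	0.144762	-0.206842	-0.418473	-0.351028	-1.017997	-0.352012	-0.624448	0.124957	-1.242055	0.228523	0.153847	-0.110606	-0.45595	0.577276	-1.709105	0.442368	0.191817	0.339965	0.381958	-0.69061	-0.277079	0.625972	0.465665	0.126931
p0004	-0.056292	-1.381212	0.193737	-1.295076	-0.62205	-0.258754	-1.972401	0.07982	0.132663	-0.097427	-0.399608	-0.340037	-1.001951	-0.17349	-0.467132	0.119983	-1.169922	0.134227	0.175104	-0.151268	-0.41751	0.586463	-1.681666	0.375929	0.261431	0.246307	0.366803	-0.68387	-0.276539	0.521582	0.491487	0.21938
p0005	0.051138	-1.263315	0.068251	-1.432982	-0.661172	-0.354699	-2.100367	0.09549	0.050874	-0.1409	-0.499835	-0.358735	-0.982014	-0.285382	-0.556264	0.064696	-1.23476	0.151452	0.141738	-0.049286	-0.34018	0.618431	-1.629312	0.426629	0.315175	0.28057	0.379869	-0.668206	-0.254862	0.615298	0.42645	0.152483
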