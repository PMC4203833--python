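statistic	V1	M1	V3	M3	V24	M24	V48	M48
Raw Tag	3637787	3680974	3615392	3572205	3738156	3537418	3606992	3623791
Distinct raw tag	132413	131270.5	136329.5	137472	123476	141350	133594	139065
Clean tag	3564408	3606840	3538677	3496245	3669009	3459807	3532683	3544671
Distinct Clean tag	64805	62922	65558	67441	60148	69463	65419	65697
All Tag Mapping to Gene	866805	830485	824184	860504	861588	872023	848985	799383
All Tag Mapping to Gene*	24.31	23.03	23.2907	24.612	23.48	25.20	24.03	22.55
Distinct AllTag Mappingto Gene	16420	15164	16026	17283	15103	17738	16828	15225
Distinct AllTag Mappingto Gene*	25.34	24.10	24.45	25.63	25.11	25.54	25.72	23.17
Unambiguous Tag Mappingto Gene	849418	812002	807144	844560	843660	855176	833944	780344
Unambiguous Tag Mappingto Gene*	23.83	22.51	22.81	24.16	22.99	24.72	23.61	22.01
Distinct Unambiguous Tag Mappingto Gene	16124	14892	15745.5	16977.5	14831	17417	16538	14953
Distinct Unambiguous Tag Mappingto Gene*	24.88	23.67	24.02	25.17	24.66	25.07	25.28	22.76
All Tag-mapped Genes	5490	5292	5479	5678	5211	5770	5586	5373
All Tag-mapped Genes**	37.55	36.19	37.47	38.83	35.64	39.46	38.20	36.74
Unambiguous Tag-mapped Genes	5260	5066	5262	5456	4974	5547	5366	5158
Unambiguous Tag-mapped Genes**	35.97	34.64	35.98	37.32	34.01	37.93	36.70	35.27
Mapping to Genome	2174138	2246229	2202715	2130624	2267612	2080664	2180584	2224846
Mapping to Genome*	61.00	62.28	62.25	60.94	61.80	60.14	61.73	62.77
Distinct Mapping to Genome	34162	33540	34798	35420	31787	36538	34302	35294
Distinct Mapping to Genome*	52.72	53.30	53.08	52.52	52.85	52.60	52.43	53.72
Unknown Tag	523464	530125	511778	505117	539809	507120	503114	520442
Unknown Tag*	14.69	14.70	14.46	14.45	14.71	14.66	14.24	14.68
Distinct Unknown Tag	14222.5	14218	14733.5	14738	13258	15187	14289	15178
Distinct Unknown Tag*	21.95	22.60	22.47	21.85	22.04	21.86	21.84	23.10
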