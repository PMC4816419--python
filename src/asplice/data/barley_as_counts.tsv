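variety	as_type	events_24h	events_48h	genes_24h	genes_48h	turnover
Bass	A3S	1710	1203	1388	1037	888
Bass	IR	1166	1033	927	849	501
Bass	A5S	823	521	725	462	537
Bass	ES	189	81	148	68
Bass	AFE	12	8	12	8
Bass	ALE	1	3	1	3
Harrington	A3S	1217	1148	1022	979	603
Harrington	IR	781	836	635	737	286
Harrington	A5S	547	559	490	511	319
Harrington	ES	74	87	66	72
Harrington	AFE	14	10	14	10
Harrington	ALE	2	1	2	1
Stirling	A3S	1447	1180	1213	1004	716
Stirling	IR	1199	1046	965	833	521
Stirling	A5S	746	627	649	565	422
Stirling	ES	130	92	101	77
Stirling	AFE	12	3	12	3
Stirling	ALE	3	3	3	3
Baudin	A3S	1504	1287	1216	1083	717
Baudin	IR	1015	897	823	728	453
Baudin	A5S	795	646	698	575	475
Baudin	ES	116	107	101	91
Baudin	AFE	8	14	8	14
Baudin	ALE	3	5	3	5
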