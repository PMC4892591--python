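site_id	species	longitude_e	latitude_n	altitude_m	reliable_start	reliable_end	n_cores	mean_sensitivity	mean_segment_length_yr
ab01	Abies forestii	100.08	29.28	4150	1825	2006	61	0.182	172.8
ab02	Abies forestii	99.93	29.15	3530	1549	2006	56	0.321	282.9
ab03	Abies forestii	99.93	28.98	3750	1697	2007	48	0.169	263.9
ab04	Abies forestii	99.27	27.37	3050	1691	2007	27	0.216	308.2
ab05	Abies forestii	99.80	27.62	3500	1593	2007	67	0.180	320.9
ab06	Abies forestii	99.30	27.33	3040	1534	2007	41	0.244	366.1
ab07	Abies forestii	99.30	27.33	3060	1791	2007	43	0.232	224.1
ab08	Abies forestii	99.02	28.04	3200	1726	2005	19	0.242	273.4
ju01	Juniperus tibetica	101.92	31.78	3500	1665	2007	40	0.344	209.1
ju02	Juniperus tibetica	99.75	28.90	3980	1649	2007	43	0.247	278.1
ju03	Juniperus tibetica	100.27	30.23	4050	1595	2007	44	0.205	331.8
ju04	Juniperus tibetica	99.03	28.37	4260	1715	2007	42	0.159	251.2
ts01	Tsuga dumosa	99.29	27.59	3150	1730	2005	49	0.249	222.1
ts02	Tsuga dumosa	98.98	28.04	3100	1707	2005	30	0.251	296.9
ts03	Tsuga dumosa	98.40	27.88	3150	1687	2005	35	0.226	286.6
pi01	Picea likiangensis	99.35	27.58	3240	1568	2005	36	0.249	285.2
pi02	Picea likiangensis	100.28	30.87	3300	1750	2007	41	0.248	201.3
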