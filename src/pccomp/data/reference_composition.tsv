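kit_label	species_label	nominal_mass	constituent_label	r_squared_pct	mean_q	ci5	ci95	category	sum_of_proportions
PC aa C30:0	PC 30:0	705	PC 16:0_14:0	83.3	0.3584	0.2248	0.5098	I	0.4404
PC aa C30:0	PC 30:0	705	PC 18:0_12:0	83.3	0.0820	0.0462	0.1495	none	0.4404
PC aa C32:0	PC 32:0	733	PC 16:0_16:0	35.3	1.0218	0.7561	1.3897	II	1.0449
PC aa C32:0	PC 32:0	733	PC 18:0_14:0	35.3	0.0231	0.0138	0.0347	none	1.0449
PC aa C32:1	PC 32:1	731	PC 14:0_18:1	95.1	0.2981	0.1773	0.5843	I	1.0650
PC aa C32:1	PC 32:1	731	PC 16:0_16:1	95.1	0.7669	0.5433	0.9891	I	1.0650
PC aa C32:2	PC 32:2	729	PC 14:0_18:2	78.9	1.2713	0.8229	1.7371	II	1.2713
PC aa C34:1	PC 34:1	759	PC 16:0_18:1	86.6	1.4159	1.1793	1.6821	II	1.4230
PC aa C34:1	PC 34:1	759	PC 18:0_16:1	86.6	0.0057	0.0028	0.0120	none	1.4230
PC aa C34:1	PC 34:1	759	PC 20:0_14:1	86.6	0.0014	0.0009	0.0022	none	1.4230
PC aa C34:2	PC 34:2	757	PC 14:0_20:2	49.4	0.0006	0.0004	0.0010	none	1.5735
PC aa C34:2	PC 34:2	757	PC 16:0_18:2	49.4	1.5482	1.2968	1.8214	II	1.5735
PC aa C34:2	PC 34:2	757	PC 18:1_16:1	49.4	0.0247	0.0155	0.0371	none	1.5735
PC aa C34:3	PC 34:3	755	PC 14:0_20:3	85.4	0.0481	0.0252	0.0729	none	1.0848
PC aa C34:3	PC 34:3	755	PC 16:0_18:3	85.4	0.4820	0.3539	0.6165	I	1.0848
PC aa C34:3	PC 34:3	755	PC 18:2_16:1	85.4	0.5547	0.3811	0.7406	I	1.0848
PC aa C34:4	PC 34:4	753	PC 14:0_20:4	53.6	0.3681	0.2438	0.5650	I	0.3681
PC aa C36:0	PC 36:0	789	PC 18:0_18:0	14.3	0.4844	0.3066	0.7470	I	0.4844
PC aa C36:1	PC 36:1	787	PC 16:0_20:1	79.0	0.0319	0.0231	0.0447	none	0.9138
PC aa C36:1	PC 36:1	787	PC 18:0_18:1	79.0	0.8819	0.7171	1.0794	II	0.9138
PC aa C36:2	PC 36:2	785	PC 16:0_20:2	57.9	0.0373	0.0226	0.0581	none	1.1031
PC aa C36:2	PC 36:2	785	PC 18:0_18:2	57.9	0.9670	0.8172	1.1362	II	1.1031
PC aa C36:2	PC 36:2	785	PC 18:1_18:1	57.9	0.0988	0.0601	0.1467	none	1.1031
PC aa C36:3	PC 36:3	783	PC 16:0_20:3	80.4	0.6060	0.3434	0.8409	I	1.1303
PC aa C36:3	PC 36:3	783	PC 18:0_18:3	80.4	0.0175	0.0100	0.0279	none	1.1303
PC aa C36:3	PC 36:3	783	PC 18:1_18:2	80.4	0.5078	0.3177	0.7643	I	1.1303
PC aa C36:4	PC 36:4	781	PC 14:0_22:4	65.2	0.0016	0.0011	0.0025	none	0.3842
PC aa C36:4	PC 36:4	781	PC 16:0_20:4	65.2	0.2943	0.2393	0.3555	I	0.3842
PC aa C36:4	PC 36:4	781	PC 18:1_18:3	65.2	0.0109	0.0033	0.0220	none	0.3842
PC aa C36:4	PC 36:4	781	PC 18:2_18:2	65.2	0.0774	0.0354	0.1558	none	0.3842
PC aa C36:5	PC 36:5	779	PC 14:0_22:5	17.2	0.0172	0.0101	0.0262	none	0.0482
PC aa C36:5	PC 36:5	779	PC 18:2_18:3	17.2	0.0310	0.0113	0.0615	none	0.0482
PC aa C36:6	PC 36:6	777	PC 14:0_22:6	32.3	0.8810	0.4947	1.2925	II	0.8810
PC aa C38:0	PC 38:0	817	PC 18:0_20:0	34.5	0.1629	0.1193	0.2153	none	0.1629
PC aa C38:3	PC 38:3	811	PC 18:0_20:3	80.7	0.6485	0.4476	0.8496	I	0.6854
PC aa C38:3	PC 38:3	811	PC 18:1_20:2	80.7	0.0197	0.0126	0.0299	none	0.6854
PC aa C38:3	PC 38:3	811	PC 18:2_20:1	80.7	0.0172	0.0070	0.0436	none	0.6854
PC aa C38:4	PC 38:4	809	PC 16:0_22:4	58.8	0.0758	0.0504	0.1059	none	0.3974
PC aa C38:4	PC 38:4	809	PC 18:0_20:4	58.8	0.2343	0.1971	0.2867	I	0.3974
PC aa C38:4	PC 38:4	809	PC 18:1_20:3	58.8	0.0808	0.0490	0.1500	none	0.3974
PC aa C38:4	PC 38:4	809	PC 18:2_20:2	58.8	0.0065	0.0028	0.0126	none	0.3974
PC aa C38:5	PC 38:5	807	PC 16:0_22:5	67.7	0.5515	0.4380	0.6725	I	0.6847
PC aa C38:5	PC 38:5	807	PC 18:1_20:4	67.7	0.0983	0.0687	0.1286	none	0.6847
PC aa C38:5	PC 38:5	807	PC 18:2_20:3	67.7	0.0349	0.0201	0.0647	none	0.6847
PC aa C38:6	PC 38:6	805	PC 16:0_22:6	77.1	1.2431	1.0168	1.5009	II	1.2621
PC aa C38:6	PC 38:6	805	PC 18:2_20:4	77.1	0.0190	0.0118	0.0279	none	1.2621
PC aa C40:3	PC 40:3	839	PC 20:0_20:3	0.2	0.4892	0.1980	0.8453	I	0.4892
PC aa C40:4	PC 40:4	837	PC 18:0_22:4	67.2	0.7065	0.4936	0.9503	I	0.8017
PC aa C40:4	PC 40:4	837	PC 20:0_20:4	67.2	0.0952	0.0644	0.1461	none	0.8017
PC aa C40:5	PC 40:5	835	PC 18:0_22:5	76.5	0.7863	0.6343	0.9819	I	0.8451
PC aa C40:5	PC 40:5	835	PC 18:1_22:4	76.5	0.0588	0.0373	0.0840	none	0.8451
PC aa C40:6	PC 40:6	833	PC 18:0_22:6	82.7	1.0540	0.8588	1.2734	II	1.1384
PC aa C40:6	PC 40:6	833	PC 18:1_22:5	82.7	0.0718	0.0429	0.1039	none	1.1384
PC aa C40:6	PC 40:6	833	PC 18:2_22:4	82.7	0.0126	0.0076	0.0186	none	1.1384
PC aa C42:6	PC 42:6	861	PC 20:0_22:6	5.9	0.8482	0.5587	1.2468	II	0.8482
PC ae C34:1	PC 33:1	745	PC 15:0_18:1	57.8	0.0988	0.0705	0.1373	none	0.1426
PC ae C34:1	PC 33:1	745	PC 17:0_16:1	57.8	0.0438	0.0307	0.0601	none	0.1426
PC ae C34:2	PC 33:2	743	PC 15:0_18:2	7.1	0.1059	0.0698	0.1541	none	0.1059
PC ae C36:1	PC 35:1	773	PC 17:0_18:1	64.4	0.2147	0.1601	0.2878	I	0.2147
PC ae C36:2	PC 35:2	771	PC 17:0_18:2	52.8	0.2275	0.1837	0.2799	I	0.2275
PC ae C36:3	PC 35:3	769	PC 15:0_20:3	49.9	0.0700	0.0458	0.0950	none	0.0700
PC ae C36:4	PC 35:4	767	PC 15:0_20:4	26.0	0.0526	0.0339	0.0793	none	0.0526
PC ae C38:3	PC 37:3	797	PC 17:0_20:3	64.5	0.3395	0.2248	0.4767	I	0.3395
PC ae C38:4	PC 37:4	795	PC 17:0_20:4	64.1	0.1978	0.1495	0.2547	none	0.1978
PC ae C38:5	PC 37:5	793	PC 17:0_20:5	2.2	0.0263	0.0145	0.0408	none	0.0263
PC ae C38:6	PC 37:6	791	PC 15:0_22:6	12.6	0.0677	0.0433	0.1084	none	0.0677
PC ae C40:1	PC 39:1	829	PC 18:2_22:6	20.3	0.5664	0.3782	0.8648	I	0.5664
PC ae C40:5	PC 39:5	821	PC 17:0_22:5	19.7	0.1234	0.0708	0.1735	none	0.1234
PC ae C40:6	PC 39:6	819	PC 17:0_22:6	56.3	0.1720	0.1216	0.2262	none	0.1720
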