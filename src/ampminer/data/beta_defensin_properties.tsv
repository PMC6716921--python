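id	length	mw	charge	pI	anomaly
VkBDic1_VARKO	44	5069.05	10	10.3026	
VkBD1_VARKO	41	4816.46	4.5	7.9826	
VkBD2_VARKO	44	4770.49	4	8.5177	
VkBD3_VARKO	68	7510.69	-1	5.635	
VkBD4_VARKO	48	5466.13	-0.5	6.1876	
VkBD5_VARKO	45	5112.8	4.5	8.5056	
VkBD6_VARKO	70	7548.7	4.5	7.9825	
VkBD7_VARKO	83	8922.43	6	8.2233	
VkBD8_VARKO	39	3850.54	2.5	7.9391	
VkBD9_VARKO	46	5087.15	7.5	9.7437	
VkBD10_VARKO	49	5346.37	0.5	6.8341	
VkBD11_VARKO	40	4130.68	-5	3.8346	
VkBD12_VARKO	61	7362.5	6	9.0239	
VkBD13_VARKO	56	6373.34	2	7.9229	
VkBD14_VARKO	53	6051.22	9.5	10.3828	
VkBD15_VARKO	42	4598.66	9.5	10.246	
VkBD16_VARKO	54	5598.25	2	7.796	
VkBD17_VARKO	47	5538.28	6	8.4828	
VkBD18_VARKO	50	5606.31	2.5	7.512	
VkBD19_VARKO	52	5871.76	-0.5	5.6992	
VkBD20_VARKO	43	4861.77	2	7.9237	
VkBD21_VARKO	38	4009.73	6.5	9.1233	
VkBD22_VARKO	42	4645.55	4.5	8.5176	
VkBD23_VARKO	104	11026.09	-3	4.6839	
VkBD24_VARKO	48	5012.86	3.5	8.2461	
VkBD25_VARKO	42	4575.41	3.5	8.2423	
VkBD26_VARKO	44	4914.62	-3	4.2446	
VkBD27_VARKO	41	4535.29	7	9.6914	
VkBD28_VARKO	45	4618.16	0	5.9979	
VkBD29_VARKO	44	4958.8	4.5	8.5135	row_implies_extra_lys
VkBD30_VARKO	44	4538.29	0	6.0306	
VkBD31_VARKO	44	5009.92	3	8.1509	
VkBD32_VARKO	41	4339.01	3.5	8.1572	
VkBD33_VARKO	44	4782.74	8.5	10.5052	
VkBD34_VARKO	84	9330.95	4.5	8.0587	
VkBD35_VARKO	47	5058.7	-5	3.9254	
VkBD36_VARKO	48	5026.65	-8	3.371	
VkBD37_VARKO	43	4702.36	-1	4.7382	
VkBD38_VARKO	44	5172.09	2.5	7.9416	
VkBD39_VARKO	111	11483.56	5	7.86	mw_misprint
VkBD40_VARKO	43	4914.68	2.5	7.9327	
VkBD41_VARKO	41	4641.48	3.5	7.9625	
VkBD42_VARKO	42	4717.47	5.5	8.8017	
VkBD43_VARKO	74	7874.1	2.5	7.65	
VkBD44_VARKO	45	5073.96	5	8.5147	
VkBD45_VARKO	38	4229.98	8	9.7441	
VkBD46_VARKO	40	4388.17	9.5	10.8323	
VkBD47_VARKO	44	5072.96	6.5	9.154	
VkBD48_VARKO	52	5934.01	13	11.9504	
VkBD49_VARKO	40	4566.32	5.5	8.814	
VkBD50_VARKO	42	4627.4	7	10.4698	
VkBD51_VARKO	40	4467.32	9	11.3419	
VkBD52_VARKO	40	4623.65	8	11.1693	
VkBD53_VARKO	40	4537.41	10	11.9738	
VkBD54_VARKO	42	4760.65	11	12.1412	
VkBD55_VARKO	56	6092.22	6.5	8.7963	
VkBD56_VARKO	44	5031.94	8.5	9.2085	
VkBD57_VARKO	40	4852.66	8.5	9.9206	
VkBD58_VARKO	44	5254.16	6.5	8.8379	
VkBD59_VARKO	40	4369.02	5.5	8.6986	
VkBD60_VARKO	44	5232.0	6.5	8.6105	
VkBD61_VARKO	44	5146.91	7	9.5242	
VkBD62_VARKO	43	4829.59	7.5	9.1865	
VkBD79_VARKO	49	5260.29	4	8.2526	
VkBD80a_VARKO	45	5112.96	5.5	8.5212	
VkBD80b_VARKO	45	5166.0	6.5	9.0493	
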