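site_i_res	site_i_body	site_j_res	site_j_body	mean_A	peaks_A	category
1463	fixed	1608	moving	29	.	interdomain
1472	fixed	1608	moving	43	.	interdomain
1485	fixed	1608	moving	59	.	interdomain
1497	fixed	1608	moving	38	.	interdomain
1504	fixed	1608	moving	52	.	interdomain
1497	fixed	1598	moving	14	.	interdomain
1504	fixed	1598	moving	25	.	interdomain
1472	fixed	1590	moving	27	.	interdomain
1472	fixed	1626	moving	36	33/39	interdomain
1497	fixed	1626	moving	27.333	24/28/30	interdomain
1504	fixed	1626	moving	44	42/46	interdomain
1472	fixed	1630	moving	36.333	33/36/40	interdomain
1504	fixed	1630	moving	45.5	42/49	interdomain
1485	fixed	1559	linker	51	.	linker
1559	linker	1608	moving	45	.	linker
1598	moving	1608	moving	30.5	27/34	intradomain
1590	moving	1608	moving	25	.	intradomain
1626	moving	1608	moving	28	.	intradomain
1630	moving	1608	moving	23	.	intradomain
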