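# Reference catalog of histone-free regions (HFRs) at the four murine Hox
# clusters, as mapped from pan-histone-H3 ChIP-chip tiling arrays of G0
# C2C12 myoblasts.  Sizes in bp; context is the genomic-context label
# assigned to each HFR (Genic, TSS, 3' end, NCT, Intergenic).
cluster	number	name	size	context
A	1	A_DOWN-1.1	5210	3' end
A	2	A_1-2.1	510	NCT
A	3	A_1-2.2	860	NCT
A	4	A_1-2.3	510	3' end
A	5	A_2-3.1	810	Intergenic
A	6	A_3-4.1	1410	3' end
A	7	A_3-4.2	660	Intergenic
A	8	A_3-4.3	510	Intergenic
A	9	A_4-5.1	2460	Intergenic
A	10	A_4-5.2	2920	Intergenic
A	11	A_5.1	650	Genic
A	12	A_6-7.1	610	Intergenic
A	13	A_6-7.2	510	Intergenic
A	14	A_7-9.1	510	Intergenic
A	15	A_7-9.2	680	Intergenic
A	16	A_7-9.3	1080	Intergenic
A	17	A_9-10.1	960	3' end
A	18	A_10-11.1	1060	Intergenic
A	19	A_10-11.2	560	NCT
A	20	A_11.1	560	Genic
A	21	A_11-13.1	1110	NCT
A	22	A_11-13.2	3810	Intergenic
A	23	A_UP.1	510	Intergenic
A	24	A_UP.2	660	Intergenic
A	25	A_UP.3	560	Intergenic
B	1	B_13-9.1	1160	Intergenic
B	2	B_13-9.2	760	Intergenic
B	3	B_13-9.3	720	Intergenic
B	4	B_13-9.4	810	Intergenic
B	5	B_9-8.1	800	Intergenic
B	6	B_7-6.1	510	NCT
B	7	B_5-4.1	510	TSS
B	8	B_4-3.1	710	TSS
B	9	B_3.1	510	Genic
B	10	B_3.2	820	Genic
B	11	B_2-1.1	560	3' end
B	12	B_2-1.2	760	Intergenic
B	13	B_2-1.3	1880	Intergenic
B	14	B_2-1.4	690	Intergenic
C	1	C_UP.26	1020	Intergenic
C	2	C_UP.27	2260	Intergenic
C	3	C_UP.28	510	Intergenic
C	4	C_UP.29	530	TSS
C	5	C_13.1	1010	Genic
C	6	C_13.2	1710	Genic
C	7	C_13-12.1	1110	Intergenic
C	8	C_12-11.1	510	Intergenic
C	9	C_12-11.2	1460	3' end
C	10	C_12-11.3	1610	NCT
C	11	C_12-11.4	510	Intergenic
C	12	C_11-10.1	510	NCT
C	13	C_11-10.2	1510	NCT
C	14	C_11-10.3	760	NCT
C	15	C_11-10.4	1260	NCT
C	16	C_11-10.5	560	TSS
C	17	C_10.1	2230	Genic
C	18	C_9.1	1010	Genic
C	19	C_9-8.1	760	Intergenic
C	20	C_9-8.2	850	Intergenic
C	21	C_8-6.1	710	3' end
C	22	C_8-6.2	1370	Intergenic
C	23	C_8-6.3	1810	Intergenic
C	24	C_8-6.4	1510	Intergenic
C	25	C_6-5.1	600	TSS
C	26	C_5-4.1	810	Intergenic
C	27	C_5-4.2	1660	Intergenic
C	28	C_5-4.3	560	Intergenic
C	29	C_5-4.4	2660	Intergenic
C	30	C_4-DOWN.1	710	3' end
C	31	C_DOWN.1	660	Intergenic
C	32	C_DOWN.2	1580	Intergenic
D	1	D_UP.13	860	Intergenic
D	2	D_UP.14	1660	Intergenic
D	3	D_13.1	2030	Genic
D	4	D_12-11.1	560	3' end
D	5	D_11-10.1	1410	Intergenic
D	6	D_11-10.2	510	Intergenic
D	7	D_10-9.1	910	3' end
D	8	D_9-8.1	2080	3' end
D	9	D_8-4.1	710	NCT
D	10	D_8-4.2	510	NCT
D	11	D_8-4.3	810	TSS
D	12	D_8-4.4	760	TSS
D	13	D_4-3.1	1510	Intergenic
D	14	D_4-3.2	1160	TSS
D	15	D_3-1.1	760	Intergenic
D	16	D_3-1.2	510	3' end
D	17	D_3-1.3	840	NCT
D	18	D_3-1.4	590	NCT
D	19	D_3-1.5	2470	NCT
D	20	D_1-DOWN.1	1360	3' end
D	21	D_DOWN.1	3680	Intergenic
D	22	D_DOWN.2	1080	Intergenic
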