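1	0	125000000	1p
1	125000000	249250621	1q
2	0	93300000	2p
2	93300000	243199373	2q
3	0	91000000	3p
3	91000000	198022430	3q
4	0	50400000	4p
4	50400000	191154276	4q
5	0	48400000	5p
5	48400000	180915260	5q
6	0	61000000	6p
6	61000000	171115067	6q
7	0	59900000	7p
7	59900000	159138663	7q
8	0	45600000	8p
8	45600000	146364022	8q
9	0	49000000	9p
9	49000000	141213431	9q
10	0	40200000	10p
10	40200000	135534747	10q
11	0	53700000	11p
11	53700000	135006516	11q
12	0	35800000	12p
12	35800000	133851895	12q
13	17900000	115169878	13q
14	17600000	107349540	14q
15	19000000	102531392	15q
16	0	36600000	16p
16	36600000	90354753	16q
17	0	24000000	17p
17	24000000	81195210	17q
18	0	17200000	18p
18	17200000	78077248	18q
19	0	26500000	19p
19	26500000	59128983	19q
20	0	27500000	20p
20	27500000	63025520	20q
21	13200000	48129895	21q
22	14700000	51304566	22q
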