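# Synthetic default genotype-profiling panel: 50 common SNV sites.
# Columns: chrom, pos (1-based), ref, alt. Replace with a panel of
# common SNPs ascertained for your own genome build and population.
1	10000000	T	G
2	11000003	G	C
3	12000006	T	C
4	13000009	A	C
5	14000012	A	G
6	15000015	C	A
7	16000018	A	T
8	17000021	T	C
9	18000024	C	G
10	19000027	C	A
11	20000030	A	C
12	21000033	C	T
13	22000036	T	C
14	23000039	T	G
15	24000042	C	G
16	25000045	T	G
17	26000048	G	T
18	27000051	G	C
19	28000054	G	A
20	29000057	T	G
21	30000060	T	C
22	31000063	A	G
1	32000066	A	T
2	33000069	G	A
3	34000072	G	A
4	35000075	G	C
5	36000078	T	C
6	37000081	G	C
7	38000084	A	C
8	39000087	T	G
9	40000090	T	G
10	41000093	C	A
11	42000096	C	G
12	43000099	C	A
13	44000102	T	C
14	45000105	A	C
15	46000108	A	C
16	47000111	A	T
17	48000114	A	C
18	49000117	C	T
19	10000120	C	A
20	11000123	G	T
21	12000126	C	G
22	13000129	A	C
1	14000132	C	G
2	15000135	T	A
3	16000138	G	A
4	17000141	C	A
5	18000144	A	T
6	19000147	C	T
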