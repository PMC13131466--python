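chr1	0	125000000	1p
chr1	125000000	249250621	1q
chr2	0	93300000	2p
chr2	93300000	243199373	2q
chr3	0	91000000	3p
chr3	91000000	198022430	3q
chr4	0	50400000	4p
chr4	50400000	191154276	4q
chr5	0	48400000	5p
chr5	48400000	180915260	5q
chr6	0	61000000	6p
chr6	61000000	171115067	6q
chr7	0	59900000	7p
chr7	59900000	159138663	7q
chr8	0	45600000	8p
chr8	45600000	146364022	8q
chr9	0	49000000	9p
chr9	49000000	141213431	9q
chr10	0	40200000	10p
chr10	40200000	135534747	10q
chr11	0	53700000	11p
chr11	53700000	135006516	11q
chr12	0	35800000	12p
chr12	35800000	133851895	12q
chr13	0	17900000	13p
chr13	17900000	115169878	13q
chr14	0	17600000	14p
chr14	17600000	107349540	14q
chr15	0	19000000	15p
chr15	19000000	102531392	15q
chr16	0	36600000	16p
chr16	36600000	90354753	16q
chr17	0	24000000	17p
chr17	24000000	81195210	17q
chr18	0	17200000	18p
chr18	17200000	78077248	18q
chr19	0	26500000	19p
chr19	26500000	59128983	19q
chr20	0	27500000	20p
chr20	27500000	63025520	20q
chr21	0	13200000	21p
chr21	13200000	48129895	21q
chr22	0	14700000	22p
chr22	14700000	51304566	22q
chrX	0	60600000	Xp
chrX	60600000	155270560	Xq
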