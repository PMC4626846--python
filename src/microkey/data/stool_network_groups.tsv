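# Published composition of the HMP stool co-occurrence network (1254 OTUs).
# One row per taxonomic group: total group size and the number of group
# members observed inside the top-centrality sets (degree top-20%,
# betweenness top-20%, degree top-10%, degree top-5%), together with the
# published hypergeometric p-values (4 d.p.) for each column.
group	total	d20_x	d20_p	b20_x	b20_p	d10_x	d10_p	d5_x	d5_p
Akkermansia	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Alistipes	72	4	0.9996	3	0.9999	1	0.9961	0	0.9781
Anaerotruncus	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Bacteroidales	4	0	0.5912	0	0.5912	0	0.3433	0	0.1865
Bacteroides	640	157	0.0000	164	0.0000	67	0.2426	24	0.9764
Bifidobacterium	2	0	0.3604	0	0.3604	0	0.1895	0	0.0980
Blautia	20	1	0.9326	1	0.9326	1	0.6085	1	0.2658
Clostridiales	13	2	0.4995	1	0.7683	1	0.3775	1	0.1358
Clostridium	21	3	0.6321	1	0.9440	2	0.3497	0	0.6643
Coprococcus	9	0	0.8670	0	0.8670	0	0.6126	0	0.3721
Dialister	7	0	0.7915	0	0.7915	0	0.5214	0	0.3035
Faecalibacterium	94	37	0.0000	34	0.0000	25	0.0000	19	0.0000
Holdemania	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Lachnospira	12	0	0.9323	0	0.9323	0	0.7180	0	0.4628
Lachnospiraceae	50	5	0.9554	5	0.9554	1	0.9681	1	0.7292
Odoribacter	10	0	0.8938	0	0.8938	0	0.6515	0	0.4039
Oscillospira	51	14	0.0670	12	0.2032	8	0.0593	5	0.0385
Parabacteroides	65	0	1.0000	1	1.0000	0	0.9991	0	0.9680
Porphyromonadaceae	3	0	0.4886	0	0.4886	0	0.2704	0	0.1434
Rikenellaceae	3	0	0.4886	0	0.4886	0	0.2704	0	0.1434
Roseburia	40	3	0.9735	4	0.9277	1	0.9219	0	0.8770
Ruminococcaceae	27	4	0.6550	3	0.8212	4	0.1230	2	0.1502
Ruminococcus	43	2	0.9959	2	0.9959	0	0.9899	0	0.8952
Subdoligranulum	36	18	0.0000	20	0.0000	14	0.0000	10	0.0000
Alcaligenaceae	7	0	0.7915	0	0.7915	0	0.5214	0	0.3035
Burkholderiales	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Catabacteriaceae	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Dorea	1	1	0.0000	0	0.2002	0	0.0997	0	0.0502
Lachnobacterium	2	0	0.3604	0	0.3604	0	0.1895	0	0.0980
Sutterella	2	0	0.3604	0	0.3604	0	0.1895	0	0.0980
Turicibacteraceae	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Eubacterium	6	0	0.7390	0	0.7390	0	0.4681	0	0.2665
Phascolarctobacterium	6	0	0.7390	0	0.7390	0	0.4681	0	0.2665
Collinsella	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
Escherichia	1	0	0.2002	0	0.2002	0	0.0997	0	0.0502
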