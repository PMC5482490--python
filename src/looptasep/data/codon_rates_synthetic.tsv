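codon	rate_per_s
AAA	3.58014564994
AAC	19.4821892941
AAG	9.77332625655
AAT	4.97391067315
ACA	11.1860783552
ACC	30.4414798328
ACG	12.3309184911
ACT	7.06161009357
AGA	8.31890993763
AGC	16.4879073591
AGG	14.624002096
AGT	9.74861894573
ATA	13.3791655538
ATC	9.45074150091
ATG	6.15639556545
ATT	5.4708728577
CAA	4.83545198955
CAC	6.89087258826
CAG	7.06864799308
CAT	9.12713464519
CCA	3.30767289074
CCC	8.97389234391
CCG	8.05360821199
CCT	18.2454153256
CGA	4.28663043168
CGC	5.13056582567
CGG	22.4644127611
CGT	7.63802532204
CTA	5.79438915983
CTC	5.81725222523
CTG	11.7349449248
CTT	5.48625535065
GAA	8.72600921568
GAC	16.8490212706
GAG	10.760631096
GAT	2.23903262816
GCA	18.3123642423
GCC	40.8038931
GCG	7.21100120626
GCT	5.77015468355
GGA	7.58145229068
GGC	8.7454666113
GGG	5.55723834574
GGT	9.27061807383
GTA	8.08370170076
GTC	6.41798120926
GTG	8.31261160758
GTT	19.8701492913
TAC	7.9658240151
TAT	6.68135984608
TCA	15.8698015237
TCC	3.43085971922
TCG	5.03511201252
TCT	4.01422027185
TGC	3.3955106559
TGG	15.384446176
TGT	13.5063357647
TTA	3.24977676498
TTC	11.3565343058
TTG	7.58172584152
TTT	10.6957220776
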