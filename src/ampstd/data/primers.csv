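gene,primer_name_f,primer_seq_f,primer_name_r,primer_seq_r,amplicon_size_bp,standard_length_bp
16S,349F,AGG CAG CAG TDR GGA AT,806R,GGA CTA CYV GGG TAT CTA AT,460,498
ITS,ITS3,CAH CGA TGA AGA ACG YRG,ITS4,TCC TSC GCT TAT TGA TAT GC,430,472
mcrA,ML-F(mcrA)32,GGT GGT GTM GGA TTC ACA CAR TAY GCW ACA GC,ML-R(mcrA)23,TTC ATT GCR TAG TTW GGR TAG TT,476,500
pmoA,A189F,GGN GAC TGG GAC TTC TGG,A682r,GAA SGC NGA GAA GAA SGC,532,572
nifH,PolF_115,TGC GAY CCS AAR GCB GAC TC,PolR_457,ATS GCC ATC ATY TCR CCG GA,362,416
nosZ,nosZ-1F,WCS YTG TTC MTC GAC AGC CAG,nosZ_1R,ATG TCG ATC ARC TGV KCR TTY TC,249,309
amoA_archaeal,Arch-amoAF,CTG AYT GGG CYT GGA CAT C,Arch-amoAR,TTC TTC TTT GTT GCC CAG TA,635,665
amoA_bacterial,amoA-1F,GGG GHT TYT ACT GGT GGT,amoA-2R,CCC CTC KGS AAA GCC TTC TTC,491,531
nirS,cd3AF,GTS AAC GTS AAG GAR ACS GG,R3cd,GAS TTC GGR TGS GTC TTG A,425,465
nirK,nirK_F1aCu,ATC ATG GTS CTG CCG CG,nirK_R3Cu,GCC TCG ATC AGR TTG TGG TT,473,513
nxrB,nxrB169f,TAC ATG TGG TGG AAC A,nxrB638r,CGG TTC TGG TCR ATC A,485,525
norB,qnorB2F,GGN CAY CAR GGN TAY GA,qnorB5R,ACC CAN AGR TGN ACN ACC CAC CA,260,284
phoD,phoD-F733,TGG GAY GAT CAY GAR GT,phoD-R1083,CTG SGC SAK SAC RTT CCA,363,377
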