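# Rule Set 1 on-target activity model coefficients (Doench et al. 2014, doi:10.1038/nbt.3026,
# supplementary coefficient table as mirrored by the reference public implementations).
# position is 1-based within the 30-mer context (4 nt upstream + 20 nt protospacer +
# 3 nt PAM + 3 nt downstream); gc_low applies per GC unit below 10 in the protospacer,
# gc_high per GC unit above 10.
feature,position,sequence,weight
intercept,,,0.59763615
gc_low,,,-0.2026259
gc_high,,,-0.1665878
nt,2,G,-0.2753771
nt,3,A,-0.3238875
nt,3,C,0.17212887
nt,4,C,-0.1006662
nt,5,C,-0.2018029
nt,5,G,0.24595663
nt,6,A,0.03644004
nt,6,C,0.09837684
nt,7,C,-0.7411813
nt,7,G,-0.3932644
nt,12,A,-0.466099
nt,15,A,0.08537695
nt,15,C,-0.013814
nt,16,A,0.27262051
nt,16,C,-0.1190226
nt,16,T,-0.2859442
nt,17,A,0.09745459
nt,17,G,-0.1755462
nt,18,C,-0.3457955
nt,18,G,-0.6780964
nt,19,A,0.22508903
nt,19,C,-0.5077941
nt,20,G,-0.4173736
nt,20,T,-0.054307
nt,21,G,0.37989937
nt,21,T,-0.0907126
nt,22,C,0.05782332
nt,22,T,-0.5305673
nt,23,T,-0.8770074
nt,24,C,-0.8762358
nt,24,G,0.27891626
nt,24,T,-0.4031022
nt,25,A,-0.0773007
nt,25,C,0.28793562
nt,25,T,-0.2216372
nt,28,G,-0.6890167
nt,28,T,0.11787758
nt,29,C,-0.1604453
nt,30,G,0.38634258
nt,2,GT,-0.6257787
nt,5,GC,0.30004332
nt,6,AA,-0.8348362
nt,6,TA,0.76062777
nt,7,GG,-0.4908167
nt,12,GG,-1.5169074
nt,12,TA,0.7092612
nt,12,TC,0.49629861
nt,12,TT,-0.5868739
nt,13,GG,-0.3345637
nt,13,TA,0.76384993
nt,13,TC,-0.5370252
nt,17,TG,-0.7981461
nt,19,GG,-0.6668087
nt,19,TC,0.35318325
nt,20,CC,0.74807209
nt,20,TG,-0.3672668
nt,21,AC,0.56820913
nt,21,CG,0.32907207
nt,21,GA,-0.8364568
nt,21,GG,-0.7822076
nt,22,TC,-1.029693
nt,23,CG,0.85619782
nt,23,CT,-0.4632077
nt,24,AA,-0.5794924
nt,24,AG,0.64907554
nt,25,AG,-0.0773007
nt,25,CG,0.28793562
nt,25,TG,-0.2216372
nt,27,GT,0.11787758
nt,29,GG,-0.69774
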