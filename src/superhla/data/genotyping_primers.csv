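name,gene,purpose,sequence
HLAA-P1,HLA-A,PCR,TCCAGGTGGACAGGTAAGGA
HLAA-P2,HLA-A,PCR,GTCACTGCCTGGGGTAGAAC
HLAB-P1,HLA-B,PCR,TGCATTCTGGGTTTCTCTACTGG
HLAB-P2,HLA-B,PCR,CACGCGAAACATCCCAATCA
HLAC-P1,HLA-C,PCR,AGGTAAGGCAAAGGGTGGGA
HLAC-P2,HLA-C,PCR,AGGCCGCCTGTACTTTTCTC
HLAA-P3,HLA-A,sequencing,ACCCTCGTCCTGCTACTCTCG
HLAB-P3,HLA-B,sequencing,ACCCTCCTCCTGCTGCTCTG
HLAC-P3,HLA-C,sequencing,CGTTGGGGATTCTCCACTCC
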