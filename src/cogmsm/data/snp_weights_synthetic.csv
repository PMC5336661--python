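snp_id,risk_allele,or,maf,locus
rs0000001,C,3.68,0.15,APOE_e4_proxy
rs0000002,T,0.62,0.08,APOE_e2_proxy
rs0000003,A,1.22,0.41,BIN1
rs0000004,G,1.18,0.19,ABCA7
rs0000005,T,0.86,0.38,CLU
rs0000006,A,1.18,0.20,CR1
rs0000007,C,0.91,0.27,CD2AP
rs0000008,T,0.94,0.31,CD33
rs0000009,G,0.90,0.34,EPHA1
rs0000010,A,1.08,0.40,MS4A4A
rs0000011,C,1.08,0.39,MS4A4E
rs0000012,T,0.90,0.42,MS4A6A
rs0000013,G,0.88,0.36,PICALM
rs0000014,A,1.11,0.28,HLA_DRB5
rs0000015,C,1.10,0.37,PTK2B
rs0000016,T,0.77,0.04,SORL1
rs0000017,G,0.91,0.22,SLC24A4_RIN3
rs0000018,A,1.07,0.48,DSG2
rs0000019,C,1.08,0.49,INPP5D
rs0000020,T,0.93,0.41,MEF2C
rs0000021,G,0.93,0.37,NME8
rs0000022,A,1.08,0.29,ZCWPW1
rs0000023,C,1.08,0.31,CELF1
rs0000024,T,1.14,0.09,FERMT2
rs0000025,G,1.12,0.08,CASS4
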