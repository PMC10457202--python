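cpg_id,chromosome,snp_maf,cross_reactive,region_class,gene
cg01,1,0.05,False,promoter,TCF7
cg02,2,0.05,False,body,RUNX1
cg03,X,NA,True,other,NA
cg04,3,0.0,True,promoter,TOX
cg05,4,0.0,False,body,SMAD3
cg06,5,NA,False,other,GRAP2
cg07,6,0.005,False,promoter,LEF1
cg08,7,0.0,False,body,FOXO3
cg09,8,NA,False,other,NA
cg10,9,0.002,False,promoter,NR3C2
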