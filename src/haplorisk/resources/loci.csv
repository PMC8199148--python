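snp_id,gene,allele_major,allele_minor,gene_order_index
rs2794521,CRP,A,G,0
rs1800947,CRP,G,C,1
rs1130864,CRP,C,T,2
rs1107946,COL1A1,G,T,0
rs1800012,COL1A1,G,T,1
rs1800795,IL6,G,C,0
rs1800796,IL6,G,C,1
rs1800797,IL6,G,A,2
rs2069827,IL6,G,T,3
rs12700386,IL6,G,C,4
rs10499563,IL6,T,C,5
rs2228570,VDR,G,A,0
rs1544410,VDR,G,T,1
rs731236,VDR,T,C,2
rs2070744,ENOS,T,C,0
rs1799983,ENOS,T,G,1
rs1800780,ENOS,A,G,2
rs3918181,ENOS,G,A,3
rs891512,ENOS,G,A,4
rs1808593,ENOS,G,T,5
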