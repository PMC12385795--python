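r_gene_id,diseases,synthetic
At_WRR9,WR,no
At_RAC1,WR,no
At_NGR1a,WR,no
Bju_WRR1,WR,no
At_WRR4a,WR,no
At_WRR4b,WR,no
At_WRR12,WR,no
At_RLM1a,BL,no
At_RLM1b,BL,no
Bna_Rlm9/4/7,BL,no
Bna_LepR3/Rlm2,BL,no
At_RPP1,DM,no
At_RPP2a,DM,no
At_RPP2b,DM,no
At_RPP4,DM,no
At_RPP7,DM,no
At_RPP8,DM,no
At_RPP13,DM,no
At_NGR1b,DM,no
Bra_Crr1a,CR,no
Bra_cRa/cRb,CR,no
At_Rpw8.1,PM,no
At_NDR1,BLS,no
syn_R01,ABS,yes
syn_R02,BLS,yes
syn_R03,FW,yes
syn_R04,GM,yes
syn_R05,PM,yes
syn_R06,SSR,yes
syn_R07,BR,yes
syn_R08,BL,yes
syn_R09,WR,yes
syn_R10,DM,yes
syn_R11,CR,yes
syn_R12,ABS,yes
syn_R13,FW,yes
syn_R14,ABS,yes
syn_R15,BLS,yes
syn_R16,FW,yes
syn_R17,GM,yes
syn_R18,PM,yes
syn_R19,SSR,yes
syn_R20,BR,yes
syn_R21,BL,yes
syn_R22,WR,yes
syn_R23,DM,yes
syn_R24,CR,yes
syn_R25,ABS,yes
syn_R26,FW,yes
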