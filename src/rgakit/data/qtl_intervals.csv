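qtl_name,species,disease,chromosome,start,end
A7,Bna,BL,A08,9926520,14644781
A8.dy09,Bna,BL,A08,9514104,15735553
A9.dy05,Bna,BL,A09,5371869,20078473
C6.dy13,Bna,BL,C06,13138327,20245793
C8,Bna,BL,C08,23938650,35120753
CRQTL-GN_2,Bna,CR,C03,1185066,2835468
Dw12,Bna,SSR,C02,3710868,6707092
Dw16,Bna,SSR,C06,28554990,35465622
Dw3,Bna,SSR,A03,15547362,16064878
LepR1,Bna,BL,A02,11756829,18651329
LRA9-1,Bna,SSR,A09,22050676,23688607
LRA9-2,Bna,SSR,A09,22050676,22586868
LRC5,Bna,SSR,C04,3065391,7930616
qFR10-1,Bna,SSR,C02,1027454,3174971
qFR10-2,Bna,SSR,C02,1099275,6816020
qFR11-1,Bna,SSR,A09,29166099,29361292
qFR11-3,Bna,SSR,C02,1027454,3174971
qSR10-1,Bna,SSR,A02,1610851,7705833
qSR10-2,Bna,SSR,A03,3131828,6786833
qSR10-3,Bna,SSR,C02,1027454,3953336
qSR11-1,Bna,SSR,A09,27128147,28071597
qSR11-2,Bna,SSR,C02,1027454,3953336
Rlm3,Bna,BL,A07,15120000,16290000
SCR-C6,Bna,CR,C06,25090000,26220000
Sll14a,Bna,SSR,C04,396764,9418160
Sll14b,Bna,SSR,C04,11691778,28720453
Sll2,Bna,SSR,A02,32458,3454175
SRA1,Bna,SSR,A01,12444829,19857639
SRA2-1,Bna,SSR,A02,16670964,20474897
SRA2-2,Bna,SSR,A02,21084362,24719312
SRA6,Bna,SSR,A06,20965425,23324273
SRA8,Bna,SSR,A08,7467851,8338138
SRA9-1,Bna,SSR,A09,22586748,26573318
SRC6-1,Bna,SSR,C06,30278840,34585422
SRC6-2,Bna,SSR,C06,30278840,34585422
SRC7,Bna,SSR,C07,29634609,31761057
TS A09,Bna,BL,A09,24341296,25991630
AcB1-A4.1,Bju,WR,A04,9446467,11808704
AcB1-A5.1,Bju,WR,A05,3795221,6894070
AcB1-A5.1,Bju,WR,B06,4226533,7156115
BjCHI1,Bju,HR,A03,9353574,21355565
LMJR1,Bju,BL,B03,498805,10675185
LMJR2,Bju,BL,B08,1,21282056
PhR2,Bju,BL,A08,21485767,24843799
PhR2,Bju,BL,B03,1554162,4778538
BRQTL-C1_1,Bol,BR,C01,14884502,16579946
BRQTL-C1_2,Bol,BR,C01,18227386,37119290
BRQTL-C3,Bol,BR,C03,19714632,22846644
BRQTL-C6,Bol,BR,C06,7423787,10466894
LepR1,Bol,BL,C02,23420917,39667823
LepR2,Bol,BL,C09,36661274,41215564
LepR4,Bol,BL,C03,35912191,49368477
Rlm1,Bol,BL,C06,20455085,36165661
Rcr6,Bni,CR,B03,6100000,6600000
Rlm6,Bju,BL,A07,28140000,28631000
Rlm6,Bju,BL,B04,19804000,22303000
Rlm13,Bna,BL,C03,2573230,5711418
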