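species,chromosome,length_mbp,is_contig,RLK,LRR-RLK,LysM-RLK,OtherReceptor-RLK,RLP,LRR-RLP,LysM-RLP,OtherReceptor-RLP,TM-CC,TNL,CNL,RNL,TX,TN,NL,RN,CN,OTHER,RPW8,Total
B. nigra,Chr01,54.73,False,74,28,4,42,10,10,0,0,24,9,0,0,4,3,3,0,0,2,2,131
B. nigra,Chr02,73.74,False,147,57,0,90,23,23,0,0,53,20,6,3,16,5,8,2,2,4,4,293
B. nigra,Chr03,59.02,False,117,44,0,73,17,17,0,0,40,22,8,0,3,9,4,2,2,6,0,230
B. nigra,Chr04,51.41,False,87,38,1,48,28,27,1,0,30,35,13,0,23,5,5,2,4,4,1,237
B. nigra,Chr05,67.89,False,132,47,0,85,29,28,1,0,29,7,3,1,12,6,11,2,1,3,1,237
B. nigra,Chr06,61.87,False,83,37,0,46,22,22,0,0,30,3,4,2,4,0,2,1,1,2,0,154
B. nigra,Chr07,59.87,False,61,33,1,27,17,17,0,0,32,4,1,3,3,1,1,0,3,2,0,128
B. nigra,Chr08,71.98,False,118,39,0,79,15,15,0,0,30,19,2,0,3,1,3,0,2,7,3,203
B. nigra,Contig005,,True,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig011,,True,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig013,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig032,,True,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig041,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig048,,True,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,1
B. nigra,Contig067,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig158,,True,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig193,,True,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,1
B. nigra,Contig296,,True,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig323,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
B. nigra,Contig353,,True,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,1
S. arvensis,Chr01,46.40,False,75,23,2,50,13,13,0,0,20,10,1,0,7,1,0,0,0,1,1,129
S. arvensis,Chr02,43.41,False,124,45,1,78,15,15,0,0,38,14,4,1,13,4,3,2,1,3,0,222
S. arvensis,Chr03,37.28,False,65,28,1,36,23,23,0,0,26,11,5,0,5,8,0,0,0,4,0,147
S. arvensis,Chr04,47.78,False,91,34,0,57,13,13,0,0,28,26,0,0,5,6,3,1,2,3,4,182
S. arvensis,Chr05,52.17,False,68,35,0,33,16,16,0,0,31,39,9,5,28,7,15,1,13,3,1,236
S. arvensis,Chr06,49.85,False,125,39,0,86,27,26,1,0,33,14,3,0,4,5,3,1,0,3,2,220
S. arvensis,Chr07,49.15,False,86,38,0,48,16,16,0,0,30,3,9,2,3,3,6,1,1,2,0,162
S. arvensis,Chr08,42.09,False,104,33,1,70,11,11,0,0,33,8,5,0,1,1,3,2,3,2,1,174
S. arvensis,Chr09,36.73,False,80,25,0,55,20,19,1,0,25,7,5,0,3,4,0,0,2,1,3,150
S. arvensis,Contig357,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
S. arvensis,Contig358,,True,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
S. arvensis,Contig452,,True,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1
S. alba,Chr01,57.15,False,55,19,2,34,7,7,0,0,17,3,0,0,2,1,1,0,0,0,0,86
S. alba,Chr02,31.68,False,55,28,1,26,11,11,0,0,35,2,2,0,0,1,0,0,1,1,0,108
S. alba,Chr03,31.00,False,78,21,0,57,0,0,0,0,15,3,0,2,0,1,1,1,0,0,0,101
S. alba,Chr04,32.85,False,62,31,0,31,2,2,0,0,33,6,1,0,11,1,4,2,1,2,3,128
S. alba,Chr05,28.50,False,60,20,1,39,10,9,1,0,12,6,2,0,2,0,0,1,1,0,0,94
S. alba,Chr06,38.87,False,60,22,1,37,7,7,0,0,20,7,1,0,6,4,3,1,1,0,1,111
S. alba,Chr07,29.24,False,65,27,0,38,9,9,0,0,23,2,1,1,2,1,0,0,0,1,2,107
S. alba,Chr08,32.51,False,48,19,1,28,14,13,1,0,16,2,4,0,4,1,1,0,0,0,0,90
S. alba,Chr09,44.42,False,79,31,0,48,13,12,1,0,18,4,2,0,2,0,1,1,2,1,1,124
S. alba,Chr10,28.29,False,60,24,0,36,8,8,0,0,18,7,0,1,6,2,3,0,2,1,0,108
S. alba,Chr11,30.85,False,48,23,0,25,7,7,0,0,23,3,2,0,0,0,0,1,2,2,1,89
S. alba,Chr12,30.69,False,62,22,0,40,15,15,0,0,17,2,0,0,2,1,0,0,1,0,0,100
S. alba,Contig191,,True,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1
S. alba,Contig373,,True,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
S. alba,Contig456,,True,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
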