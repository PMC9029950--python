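marker,pos_pos,pos_neg,pos_partial,partial_pos,partial_partial,partial_neg,neg_pos,neg_partial,neg_neg
HLA-DR,115,9,0,11,21,1,0,4,39
CD117,61,7,0,22,35,3,0,6,66
CD34,90,3,0,10,40,2,0,5,50
CD38,135,35,0,7,18,2,0,1,2
CD16,0,0,0,0,3,1,0,1,195
CD11b,2,1,0,2,10,17,0,3,165
CD13,63,3,0,25,51,2,0,20,36
CD33,84,4,0,22,40,6,0,7,37
CD15,5,4,0,2,20,25,0,3,141
CD64,15,3,0,12,26,9,0,12,123
CD14,0,0,0,1,0,5,0,0,194
CD5,3,2,0,0,1,4,0,2,188
CD10,43,0,0,3,4,0,0,3,147
CD22,31,6,0,2,14,2,0,8,137
CD20,10,3,0,3,13,6,0,5,160
CD19,49,1,0,1,10,0,0,20,119
CD7,17,11,0,3,18,4,0,3,144
CD2,4,2,0,0,2,6,0,1,185
CD56,6,1,0,3,16,8,0,1,165
CD3,0,1,0,0,2,2,0,0,195
CD4,6,1,0,4,13,23,0,12,141
CD8,3,0,0,0,7,3,0,2,185
MPO,46,2,0,17,28,7,0,12,88
CD79a,28,9,0,3,13,1,0,19,127
cCD3,3,3,0,0,2,1,0,1,190
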