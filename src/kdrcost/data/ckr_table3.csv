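experiment,cage_id,generation,n_SS,n_RS,n_RR,n
CKR,A1,1,0,90,0,90
CKR,A1,3,30,43,17,90
CKR,A1,5,30,48,12,90
CKR,A1,7,38,46,6,90
CKR,A1,9,37,34,19,90
CKR,A2,1,0,90,0,90
CKR,A2,3,17,51,22,90
CKR,A2,5,26,50,14,90
CKR,A2,7,35,45,10,90
CKR,A2,9,42,45,2,89
CKR,B1,1,0,90,0,90
CKR,B1,3,26,41,23,90
CKR,B1,5,30,48,12,90
CKR,B1,7,42,42,6,90
CKR,B1,9,52,31,4,87
CKR,B2,1,0,90,0,90
CKR,B2,3,38,41,11,90
CKR,B2,5,40,37,13,90
CKR,B2,7,48,39,3,90
CKR,B2,9,61,26,3,90
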