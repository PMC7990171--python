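experiment,cage_id,generation,n_SS,n_RS,n_RR,n
KR,A1,1,6,84,0,90
KR,A1,3,33,45,11,89
KR,A1,5,28,46,15,89
KR,A1,7,38,45,2,85
KR,A1,9,106,65,7,178
KR,A2,1,6,84,0,90
KR,A2,3,26,54,9,89
KR,A2,5,29,45,14,88
KR,A2,7,41,39,7,87
KR,A2,9,54,102,24,180
KR,B1,1,9,79,0,88
KR,B1,3,23,46,19,88
KR,B1,5,40,31,18,89
KR,B1,7,38,42,9,89
KR,B1,9,44,36,10,90
KR,B2,1,9,79,0,88
KR,B2,3,26,39,23,88
KR,B2,5,36,45,8,89
KR,B2,7,44,37,12,93
KR,B2,9,38,45,7,90
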