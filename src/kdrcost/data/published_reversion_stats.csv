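experiment,cage_id,generation,n,f_SS,f_RS,f_RR,e_SS,e_RS,e_RR,p_S,p_R,hwe_p,drift_p,flag
KR,A1,1,90,0.07,0.93,0.00,,,,0.53,0.47,,,exact
KR,A2,1,90,0.07,0.93,0.00,,,,0.53,0.47,,,exact
KR,B1,1,88,0.10,0.90,0.00,,,,0.55,0.45,,,exact
KR,B2,1,88,0.10,0.90,0.00,,,,0.55,0.45,,,exact
KR,A1,3,89,0.37,0.51,0.12,0.39,0.47,0.14,0.62,0.38,0.015,0.000,exact
KR,A1,5,89,0.31,0.52,0.17,0.33,0.49,0.18,0.57,0.43,0.142,0.002,exact
KR,A1,7,85,0.45,0.53,0.02,0.51,0.41,0.08,0.71,0.29,0.000,0.000,exact
KR,A1,9,178,0.60,0.37,0.04,0.61,0.34,0.05,0.78,0.22,0.006,0.000,exact
KR,A2,3,89,0.29,0.61,0.10,0.36,0.48,0.16,0.60,0.40,0.005,0.000,exact
KR,A2,5,88,0.33,0.51,0.16,0.34,0.49,0.17,0.59,0.42,0.564,0.273,allele_cell_inconsistent
KR,A2,7,87,0.47,0.45,0.08,0.50,0.42,0.09,0.70,0.30,0.003,0.000,exact
KR,A2,9,180,0.30,0.57,0.13,0.34,0.49,0.17,0.58,0.42,0.000,0.000,exact
KR,B1,3,88,0.26,0.52,0.22,0.28,0.49,0.23,0.52,0.48,0.378,0.047,exact
KR,B1,5,89,0.50,0.35,0.20,0.39,0.47,0.14,0.62,0.38,0.000,0.000,genotype_cell_inconsistent
KR,B1,7,89,0.43,0.47,0.10,0.44,0.45,0.11,0.66,0.34,0.244,0.011,exact
KR,B1,9,90,0.50,0.40,0.11,0.48,0.43,0.10,0.69,0.31,0.330,0.059,genotype_cell_inconsistent
KR,B2,3,88,0.30,0.44,0.26,0.27,0.50,0.23,0.52,0.48,0.152,0.023,exact
KR,B2,5,89,0.41,0.50,0.09,0.44,0.44,0.12,0.66,0.34,0.000,0.000,genotype_cell_inconsistent
KR,B2,7,93,0.47,0.40,0.13,0.45,0.44,0.11,0.67,0.33,0.391,0.189,exact
KR,B2,9,90,0.42,0.50,0.08,0.45,0.44,0.11,0.67,0.33,0.197,0.480,exact
CKR,A1,1,90,0.00,1.00,0.00,,,,0.50,0.50,,,exact
CKR,A2,1,90,0.00,1.00,0.00,,,,0.50,0.50,,,exact
CKR,B1,1,90,0.00,1.00,0.00,,,,0.50,0.50,,,exact
CKR,B2,1,90,0.00,1.00,0.00,,,,0.50,0.50,,,exact
CKR,A1,3,90,0.33,0.48,0.19,0.33,0.49,0.19,0.57,0.43,0.047,0.000,exact
CKR,A1,5,90,0.33,0.53,0.13,0.36,0.48,0.16,0.60,0.40,0.184,0.057,exact
CKR,A1,7,90,0.40,0.51,0.07,0.46,0.44,0.11,0.68,0.32,0.014,0.000,genotype_cell_inconsistent
CKR,A1,9,90,0.41,0.38,0.21,0.37,0.47,0.17,0.60,0.40,0.001,0.000,exact
CKR,A2,3,90,0.19,0.57,0.24,0.22,0.50,0.28,0.47,0.53,0.142,0.059,exact
CKR,A2,5,90,0.29,0.56,0.15,0.32,0.49,0.19,0.57,0.43,0.116,0.000,genotype_cell_inconsistent
CKR,A2,7,90,0.39,0.50,0.11,0.41,0.46,0.13,0.64,0.36,0.046,0.000,exact
CKR,A2,9,89,0.47,0.51,0.02,0.53,0.40,0.08,0.73,0.27,0.002,0.000,allele_cell_inconsistent
CKR,B1,3,90,0.29,0.46,0.26,0.27,0.50,0.24,0.52,0.48,0.340,0.164,exact
CKR,B1,5,90,0.33,0.53,0.13,0.36,0.48,0.16,0.60,0.40,0.018,0.000,exact
CKR,B1,7,90,0.47,0.47,0.07,0.49,0.42,0.09,0.70,0.30,0.020,0.000,exact
CKR,B1,9,87,0.60,0.36,0.05,0.60,0.35,0.05,0.78,0.22,0.029,0.000,exact
CKR,B2,3,90,0.42,0.46,0.12,0.42,0.45,0.12,0.65,0.35,0.000,0.000,exact
CKR,B2,5,90,0.44,0.41,0.14,0.42,0.45,0.12,0.65,0.35,0.378,0.506,exact
CKR,B2,7,90,0.54,0.44,0.03,0.57,0.36,0.07,0.75,0.25,0.002,0.000,genotype_cell_inconsistent
CKR,B2,9,90,0.68,0.29,0.03,0.68,0.29,0.03,0.82,0.18,0.035,0.000,exact
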