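patient,peep_cmH2O,alpha,auc_abmps_cmH2Os,auc_abm_cmH2Os,auc_dsa_cmH2Os,ape_pct
S1,5,0.51,5.35,0.37,5.35,0.14
S1,10,0.54,4.02,0.35,4.02,0.09
S1,15,0.57,3.33,0.36,3.33,0.06
S2,5,0.63,3.11,0.50,3.11,0.13
S2,10,0.64,2.91,0.49,2.91,0.10
S2,15,0.63,2.86,0.45,2.86,0.19
S3,5,0.62,2.89,0.42,2.89,0.11
S3,10,0.63,2.58,0.41,2.58,0.08
S3,15,0.63,2.47,0.38,2.47,0.15
S4,5,0.45,10.00,0.40,10.00,0.21
S4,10,0.47,8.05,0.40,8.05,0.16
S4,15,0.50,6.77,0.41,6.77,0.15
S5,5,0.46,8.82,0.41,8.82,0.42
S5,10,0.50,6.48,0.39,6.48,0.23
S5,15,0.54,4.30,0.37,4.30,0.26
S6,5,0.63,3.03,0.46,3.03,0.07
S6,10,0.64,2.72,0.44,2.72,0.04
S6,15,0.64,2.70,0.44,2.70,0.03
S7,5,0.66,1.80,0.34,1.80,0.03
S7,10,0.64,2.03,0.35,2.03,0.02
S7,15,0.59,2.86,0.34,2.86,0.03
S8,5,0.56,3.76,0.37,3.76,0.04
S8,10,0.58,3.20,0.36,3.20,0.03
S8,15,0.58,3.11,0.36,3.11,0.02
S9,5,0.53,5.96,0.48,5.96,0.04
S9,10,0.58,4.46,0.49,4.46,0.02
S9,15,0.60,3.77,0.49,3.77,0.01
S10,5,0.59,3.76,0.47,3.76,0.07
S10,10,0.61,3.20,0.45,3.20,0.06
S10,15,0.62,3.10,0.46,3.10,0.04
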