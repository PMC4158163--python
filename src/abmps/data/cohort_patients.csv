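patient,sex,age,diagnoses,auto_peep_cmH2O
S1,Female,61,Peritonitis;COPD,10
S2,Male,22,Trauma,12
S3,Male,55,Aspiration,10
S4,Male,88,Pneumonia;COPD,10
S5,Male,59,Pneumonia;COPD,12
S6,Male,69,Trauma,11
S7,Male,56,Legionnaires,7.5
S8,Female,45,Aspiration,12
S9,Male,37,H1N1;COPD,12
S10,Male,56,Legionnaires;COPD,3
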