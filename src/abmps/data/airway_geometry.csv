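generation,diameter_mm,length_mm
-1,9,330
0,18,120
1,12.20,48
2,8.30,19
3,5.60,8
4,4.50,13
5-16,3.50-0.60,10.70-1.70
17-22,0.57-0.43,1.50-0.63
23,0.40,0.50
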