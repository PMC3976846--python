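index,name,abbreviation,size,mcc,pe,fr,rank
1,Lip color,LC,4,0.9257,0.1688,0.9480,24
2,Tongue color,Tc,4,0.9293,0.1813,0.9487,25
3,Appearance of tongue-1,At1,3,0.8123,0.5808,0.8550,16
4,Appearance of tongue-2,At2,5,0.9712,0.2998,0.9592,27
5,Coated tongue color,Ctc,3,0.8589,0.1914,0.9126,21
6,Texture of coated tongue,Tct,7,0.9039,0.2518,0.9298,23
7,Position of coated tongue,Pct,5,0.9629,0.2685,0.9578,26
8,The color of complexion,Coc,8,0.6396,2.7350,0.5790,6
9,Whole body condition,Wbc,8,0.9326,1.0378,0.8749,19
10,Odor,Od,1,0.6948,0.6055,0.7941,13
11,Chilly,Ch,1,0.6011,0.4767,0.7586,10
12,Hectic fever,Hf,1,0.7890,0.4248,0.8571,17
13,Fever,Fe,1,0.7304,0.2969,0.8391,15
14,Sweating,St,2,0.6270,0.4875,0.7706,11
15,Facial features,Ff,13,0.2177,5.6792,0.1088,1
16,Cardiothoracic condition,Ca,4,0.4923,1.2036,0.6402,8
17,Sternocostal and abdominal pain,Sap,16,0.4010,1.6943,0.5513,5
18,Diet,Diet,7,0.2937,1.7266,0.4948,3
19,Defecate and urine,Du,10,0.4016,1.7268,0.5488,4
20,Sleep,Slp,2,0.4382,0.9854,0.6324,7
21,Emotion,NEs,3,0.5141,1.1600,0.6549,9
22,Skin of the limbs,Sl,10,0.2091,2.4312,0.3905,2
23,Bump in ribs,Bir,1,0.6543,0.5541,0.7784,12
24,Ascites,Ass,1,0.7279,0.4304,0.8260,14
25,Pleural effusion,Pe,1,0.7894,0.2301,0.8745,18
26,Pulse condition in left,Pcle,13,0.8630,0.3003,0.9051,20
27,Pulse condition in right,Pcrt,13,0.8716,0.2556,0.9133,22
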