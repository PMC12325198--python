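name,region,x,y
Fp1,F,-0.1414,0.9899
Fpz,F,0.0000,1.0000
Fp2,F,0.1414,0.9899
AF7,F,-0.7834,0.5926
AF3,F,-0.3711,0.7584
AF4,F,0.3711,0.7584
AF8,F,0.7834,0.5926
F7,F,-0.8603,0.4445
F5,F,-0.6339,0.5213
F3,F,-0.4075,0.5688
F1,F,-0.1811,0.5940
Fz,F,0.0000,0.6000
F2,F,0.1811,0.5940
F4,F,0.4075,0.5688
F6,F,0.6339,0.5213
F8,F,0.8603,0.4445
FT7,LT,-0.9284,0.2222
FC5,F,-0.6841,0.2607
FC3,F,-0.4398,0.2844
FC1,F,-0.1954,0.2970
FC2,F,0.1954,0.2970
FC4,F,0.4398,0.2844
FC6,F,0.6841,0.2607
FT8,RT,0.9284,0.2222
T7,LT,-0.9500,0.0000
C3,P,-0.4500,0.0000
C1,P,-0.2000,0.0000
Cz,P,0.0000,0.0000
C2,P,0.2000,0.0000
C4,P,0.4500,0.0000
T8,RT,0.9500,0.0000
TP7,LT,-0.9284,-0.2222
CP5,P,-0.6841,-0.2607
CP3,P,-0.4398,-0.2844
CP1,P,-0.1954,-0.2970
CPz,P,0.0000,-0.3000
CP2,P,0.1954,-0.2970
CP4,P,0.4398,-0.2844
CP6,P,0.6841,-0.2607
TP8,RT,0.9284,-0.2222
P7,P,-0.8603,-0.4445
P5,P,-0.6339,-0.5213
P3,P,-0.4075,-0.5688
P1,P,-0.1811,-0.5940
Pz,P,0.0000,-0.6000
P2,P,0.1811,-0.5940
P4,P,0.4075,-0.5688
P6,P,0.6339,-0.5213
P8,P,0.8603,-0.4445
PO7,O,-0.7834,-0.5926
PO5,O,-0.5772,-0.6951
PO3,O,-0.3711,-0.7584
POz,O,0.0000,-0.8000
PO4,O,0.3711,-0.7584
PO6,O,0.5772,-0.6951
PO8,O,0.7834,-0.5926
O1,O,-0.1414,-0.9899
Oz,O,0.0000,-1.0000
O2,O,0.1414,-0.9899
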