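aa,hydropathy,volume,pI
A,1.8,88.6,6.00
C,2.5,108.5,5.07
D,-3.5,111.1,2.77
E,-3.5,138.4,3.22
F,2.8,189.9,5.48
G,-0.4,60.1,5.97
H,-3.2,153.2,7.59
I,4.5,166.7,6.02
K,-3.9,168.6,9.74
L,3.8,166.7,5.98
M,1.9,162.9,5.74
N,-3.5,114.1,5.41
P,-1.6,112.7,6.30
Q,-3.5,143.8,5.65
R,-4.5,173.4,10.76
S,-0.8,89.0,5.68
T,-0.7,116.1,5.60
V,4.2,140.0,5.96
W,-0.9,227.8,5.89
Y,-1.3,193.6,5.66
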