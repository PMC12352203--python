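code,freq
A,0.086
R,0.047
N,0.044
D,0.058
C,0.015
Q,0.038
E,0.062
G,0.078
H,0.022
I,0.057
L,0.088
K,0.062
M,0.021
F,0.040
P,0.045
S,0.060
T,0.057
W,0.014
V,0.070
Y,0.036
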