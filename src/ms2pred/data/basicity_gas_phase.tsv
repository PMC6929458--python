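# gas-phase basicity of amino acids (kcal/mol, Harrison 1997), scale-version: 1
A	205.9
C	206.2
D	208.6
E	212.1
F	212.1
G	202.7
H	223.7
I	210.8
K	221.8
L	209.6
M	213.3
N	212.8
P	212.8
Q	214.2
R	237.0
S	207.6
T	211.7
V	208.8
W	216.1
Y	213.1
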