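# Formal side-chain charge at neutral pH: K = R = +1, D = E = -1,
# histidine taken as 0 (mostly deprotonated at pH 7); all others 0.
A	0
R	1
N	0
D	-1
C	0
Q	0
E	-1
G	0
H	0
I	0
L	0
K	1
M	0
F	0
P	0
S	0
T	0
W	0
Y	0
V	0
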