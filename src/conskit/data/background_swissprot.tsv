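# Proteome-wide average amino-acid composition (Swiss-Prot release statistics),
# used as the default background probability q_k for relative-entropy scoring.
# Values are percent frequencies; they are renormalized to sum to 1 on load.
A	8.25
C	1.38
D	5.46
E	6.72
F	3.86
G	7.08
H	2.27
I	5.91
K	5.80
L	9.65
M	2.41
N	4.06
P	4.74
Q	3.93
R	5.53
S	6.64
T	5.35
V	6.86
W	1.10
Y	2.92
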