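# VTML200 amino-acid similarity matrix
# Log-odds scores at 200 PAM in half-bit units, rounded to integers,
# computed from the VT reversible substitution model (exchangeabilities
# and equilibrium frequencies) via matrix exponentiation.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A   2  -1   0   0  -1  -1   0   1  -2   0   0   0  -1  -2   0   1   1  -5  -2   0
R  -1   5  -1  -1  -4   1   0  -1  -1  -2  -1   2  -2  -3  -1  -1  -1  -5  -3  -2
N   0  -1   5   1  -4   0   0   0   0  -2  -2   0  -3  -3  -2   1   0  -7  -3  -2
D   0  -1   1   5  -5   0   2   0  -2  -3  -3   0  -4  -4  -1   0  -1  -7  -4  -2
C  -1  -4  -4  -5  11  -5  -5  -3  -6  -3  -3  -5  -4  -3  -5  -2  -2  -8  -4  -2
Q  -1   1   0   0  -5   5   1  -1   0  -2  -1   1  -2  -3  -1   0  -1  -6  -3  -2
E   0   0   0   2  -5   1   3   0  -2  -2  -2   1  -3  -3  -1   0   0  -6  -3  -1
G   1  -1   0   0  -3  -1   0   4  -3  -2  -2  -1  -3  -3  -1   1  -1  -6  -4  -2
H  -2  -1   0  -2  -6   0  -2  -3   9  -3  -3  -1  -4  -3  -3  -2  -2  -6   0  -3
I   0  -2  -2  -3  -3  -2  -2  -2  -3   3   2  -2   1   0  -2  -1   0  -4  -2   2
L   0  -1  -2  -3  -3  -1  -2  -2  -3   2   2  -1   2   1  -2  -1   0  -4  -1   2
K   0   2   0   0  -5   1   1  -1  -1  -2  -1   3  -2  -3  -1   0   0  -6  -3  -1
M  -1  -2  -3  -4  -4  -2  -3  -3  -4   1   2  -2   7   0  -3  -2  -1  -5  -2   1
F  -2  -3  -3  -4  -3  -3  -3  -3  -3   0   1  -3   0   6  -3  -2  -2  -2   2   0
P   0  -1  -2  -1  -5  -1  -1  -1  -3  -2  -2  -1  -3  -3   6   0  -1  -6  -4  -2
S   1  -1   1   0  -2   0   0   1  -2  -1  -1   0  -2  -2   0   2   1  -5  -2  -1
T   1  -1   0  -1  -2  -1   0  -1  -2   0   0   0  -1  -2  -1   1   3  -5  -2   0
W  -5  -5  -7  -7  -8  -6  -6  -6  -6  -4  -4  -6  -5  -2  -6  -5  -5  12  -2  -5
Y  -2  -3  -3  -4  -4  -3  -3  -4   0  -2  -1  -3  -2   2  -4  -2  -2  -2   8  -2
V   0  -2  -2  -2  -2  -2  -1  -2  -3   2   2  -1   1   0  -2  -1   0  -5  -2   2
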