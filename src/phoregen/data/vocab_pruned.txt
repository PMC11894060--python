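#
%10
%11
%12
(
)
-
1
2
3
4
5
6
7
8
9
<
=
B
Br
C
Cl
F
I
N
O
P
S
[B-]
[BH-]
[BH2-]
[BH3-]
[B]
[C+]
[C-]
[CH+]
[CH-]
[CH2+]
[CH2]
[CH]
[F+]
[H]
[I+]
[IH2]
[IH]
[N+]
[N-]
[NH+]
[NH-]
[NH2+]
[NH3+]
[N]
[O+]
[O-]
[OH+]
[O]
[P+]
[PH+]
[PH2+]
[PH]
[S+]
[S-]
[SH+]
[SH]
[Se+]
[SeH+]
[SeH]
[Se]
[Si-]
[SiH-]
[SiH2]
[SiH]
[Si]
[b-]
[bH-]
[c+]
[c-]
[cH+]
[cH-]
[n+]
[n-]
[nH+]
[nH]
[o+]
[s+]
[sH+]
[se+]
[se]
b
c
n
o
p
s
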