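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
[Br-]
[Br+2]
[C+]
[C-]
[CH+]
[CH-]
[CH2+]
[CH2]
[CH]
[Cl+]
[Cl-]
[Cl+3]
[Cl+2]
[F-]
[F+]
[H]
[I+]
[I+2]
[I+3]
[IH2]
[IH]
[I-]
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
[P-]
[P+]
[PH+]
[PH2+]
[PH]
[S+]
[S-]
[SH+]
[SH]
[Se-]
[Se+]
[SeH+]
[SeH]
[Se]
[SeH2]
[Si-]
[SiH-]
[SiH2]
[SiH]
[Si]
[SH-]
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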