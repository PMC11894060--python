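# Topological pharmacophore feature definitions, one SMARTS per line: <family><TAB><SMARTS>
# Family order (0-7) fixes the fingerprint bit layout; do not reorder.
acceptor	[$([OX2H1;+0]),$([OX2H0;+0;!$(O=*)]),$([OX1;+0]),$([O;-1;!$(*~[+])])]
acceptor	[$([NX3;H0;+0;v3;!$(N~[O,S,P]);!$(N-a);!$(N-C=[O,N,S])]),$([nX2;H0;+0]),$([NX2;H0;+0;!$(N=O)]),$([NX1;+0])]
acceptor	[$([SX2;H0;+0;v2]),$([SX1;+0;!$(S=*)])]
donor	[$([N;!H0;+0;!$(N-C=[O,S])]),$([N;!H0;+0;$(N-C=[O,S]);!$(N(-C=O)-C=O)])]
donor	[$([OX2;H1;+0]),$([SX2;H1;+0]),$([nX3;H1;+0]),$([NX3;H1,H2;+1])]
aromatic	a1aaaaa1
aromatic	a1aaaa1
pos_ionizable	[$([NX3;H2;+0;!$(N-[!#6]);!$(N-C=[O,N,S])]),$([NX3;H1;+0](-[#6;!$(C=*)])-[#6;!$(C=*)]),$([NX3;H0;+0](-[#6;!$(C=*)])(-[#6;!$(C=*)])-[#6;!$(C=*)])]
pos_ionizable	[$([N;+1;!$(N=O);!$(N-[O;-1])]),$([n;+1])]
pos_ionizable	[$([NX3]-[CX3](=[NX2])-[NX3]),$([NX2]=[CX3](-[NX3])-[NX3])]
neg_ionizable	[$([CX3](=O)[OX2H1]),$([CX3](=O)[OX1;-1])]
neg_ionizable	[$([SX4](=O)(=O)[OX2H1]),$([SX4](=O)(=O)[OX1;-1]),$([PX4](=O)[OX2H1]),$([PX4](=O)[OX1;-1])]
neg_ionizable	[$([O;-1;!$(O~[+])]),$([S;-1;!$(S~[+])])]
hydrophobe	[CX4;H3;$(C-[#6;!$(C=[O,N,S])])]
hydrophobe	[CX4;H2;$(C(-[CX4])-[CX4])]
hydrophobe	[$([Cl;X1;$(Cl-[#6])]),$([Br;X1;$(Br-[#6])]),$([I;X1;$(I-[#6])])]
hydrophobe	[SX2;H0;$(S(-[#6])-[#6])]
lumped_hydrophobe	[C;R]1[C;R][C;R][C;R][C;R][C;R]1
lumped_hydrophobe	[C;R]1[C;R][C;R][C;R][C;R]1
lumped_hydrophobe	c1ccccc1
zn_binder	[$([SX2;H1]),$([S;-1;X1])]
zn_binder	[$([OX1]=C-[OX2H1]),$([OX2H1]-C=[OX1]),$([OX1]=C-[O;-1]),$([O;-1]-C=[OX1])]
zn_binder	[$([NX3;H1]-C(=[OX1])-[OX2H1,NX3])]
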