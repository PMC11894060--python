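# Medicinal-chemistry structural alerts applied during screening triage.
# One record per line: <name><TAB><SMARTS>. A molecule matching any pattern
# is removed at the drug-likeness stage.
acyl_halide	[CX3](=O)[F,Cl,Br,I]
aldehyde	[CX3H1](=O)[#6]
alkyl_halide_reactive	[CH2X4][Br,I]
anhydride	[CX3](=O)O[CX3](=O)
azo	[#6]N=N[#6]
aziridine	C1CN1
diazo	[N+]=[N-]
disulfide	[#6]SS[#6]
epoxide	C1OC1
hydrazine	[NX3][NX3]
isocyanate	N=C=O
michael_acceptor_nitrile	C=CC#N
michael_acceptor_carbonyl	[CX3]=[CX3][CX3](=O)[!N]
nitro	[N+](=O)[O-]
nitroso	[#6][NX2]=O
n_oxide_acyclic	[NX3+][O-]
peroxide	[OX2][OX2]
phosphorus_halide	P[F,Cl,Br,I]
quaternary_carbon_halide	[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]
sulfonyl_halide	S(=O)(=O)[F,Cl,Br,I]
thioester	[#6]C(=O)S[#6]
thiourea	NC(=S)N
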