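# Curated structural-alert substructure patterns, v1.
# One SMARTS pattern and a name per line, whitespace separated; "#" comments.
# A hand-curated subset of the widely used reactive/toxicophore alert classes
# (nitro groups, Michael acceptors, reactive carbonyls, alkylators, ...).
# Replaceable by any file in the same format; the full RDKit Brenk filter
# catalog can be selected at run time instead (source="rdkit-brenk").
[N+](=O)[O-]	nitro_group
N=[N+]=[N-]	azide
N=N	azo_group
[NH]-[NH2]	hydrazine
C=[N+]=[N-]	diazo
[N;!$(N=O)]-[OH]	hydroxylamine
[CX3H1](=O)	aldehyde
[CX3](=O)[CX3](=O)	1,2-dicarbonyl
C=[CH1]-[CX3]=[OX1]	michael_acceptor_vinyl_carbonyl
[CX3]=[CX3]-[CX3](=O)[OX2H0]	acrylate_ester
C1OC1	epoxide
C1NC1	aziridine
[C;X4][Cl,Br,I]	alkyl_halide
[CX3](=O)[Cl,Br,I]	acyl_halide
S(=O)(=O)[Cl,Br,I]	sulfonyl_halide
[OX2]S(=O)(=O)[#6]	sulfonate_ester
[SH]	thiol
S-S	disulfide
C=C=C	allene
C#C-[CX3]=[OX1]	propiolate
N=C=O	isocyanate
N=C=S	isothiocyanate
[CX3](=S)	thiocarbonyl
C(=O)OC(=O)	acid_anhydride
[#6]-[N+]#[C-]	isonitrile
[#6]O[OX2H]	hydroperoxide
[OX2]-[OX2]	peroxide
[#6]=[N;!R]-[N;!R]	hydrazone_acyclic
C=[N;!R]-[OX2]	oxime_ether
[#7]-[N+](=O)[O-]	nitroso_amine_like
[#6]-[Hg,Pb,As,Sb,Se,Te]	heavy_metalloid_bond
[#6]=[CH2;!R]	terminal_exocyclic_alkene
c1ccc2c(c1)ccc1ccccc12	polycyclic_anthracene_like
[NX3]-[CX3]=[CX3]	enamine
[OX2H]-[CX3]=[CX3]	enol
c-[N+](=O)[O-]	aromatic_nitro
[nH0]1cccc1[CH2][Cl,Br,I]	heteroaryl_methyl_halide
[#6][C;X3](=O)[C;X4][Cl,Br,I]	alpha_halo_ketone
S(=O)(=O)O[#6]	sulfate_ester
[P;!$(P(=O)([OX2H,OX1-,OX2])([OX2H,OX1-,OX2])[OX2H,OX1-,OX2])](=O)	reactive_phosphorus
[I]	iodine_substituent
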