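# Curated well-known small molecules for structure-path tests.
# One SMILES and an id per line; includes nitro-group compounds for
# structural-alert coverage.
CCO ethanol
C methane
c1ccccc1 benzene
CC(=O)Oc1ccccc1C(=O)O aspirin
CN1C=NC2=C1C(=O)N(C)C(=O)N2C caffeine
CC(=O)Nc1ccc(O)cc1 paracetamol
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
c1ccc2c(c1)ccc1ccccc12 anthracene
[O-][N+](=O)c1ccccc1 nitrobenzene
CC1=CC(=O)C=CC1=O methylbenzoquinone
OC(=O)c1ccccc1O salicylic_acid
Cn1cnc(c1C)[N+](=O)[O-] nitroimidazole_core
CCN(CC)CCNC(=O)c1ccc(N)cc1 procainamide
OCC1OC(O)C(O)C(O)C1O glucose
CN1CCC[C@H]1c1cccnc1 nicotine
CC(N)Cc1ccccc1 amphetamine
NC(=O)c1ccncc1 isonicotinamide
OC(=O)CC(O)(CC(=O)O)C(=O)O citric_acid
CSCCC(N)C(=O)O methionine
Clc1ccccc1 chlorobenzene
C=CC(=O)OC methyl_acrylate
O=CC=C acrolein
NCCCC(N)C(=O)O ornithine
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1 salbutamol
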