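# simmap moiety catalog, version simmap-90.v1
#
# Ordered table of 90 functional groups in the spirit of checkmol's
# functional-group classification. Bit k of a moiety fingerprint is set
# iff pattern k (SMARTS) has at least one substructure match. The order
# is fixed and versioned; edit only by bumping the version.
version: simmap-90.v1
groups:
  - {name: cation, smarts: "[*+;!$([N+](=O)[O-])]"}
  - {name: anion, smarts: "[*-;!$([O-][N+]=O)]"}
  - {name: carbonyl, smarts: "[CX3]=[OX1]"}
  - {name: aldehyde, smarts: "[CX3H1]=[OX1]"}
  - {name: ketone, smarts: "[#6][CX3](=[OX1])[#6]"}
  - {name: thiocarbonyl, smarts: "[CX3]=[SX1]"}
  - {name: imine, smarts: "[CX3]=[NX2]"}
  - {name: hydrazone, smarts: "[CX3]=[NX2][NX3]"}
  - {name: oxime, smarts: "[CX3]=[NX2][OX2H]"}
  - {name: oxime ether, smarts: "[CX3]=[NX2][OX2][#6]"}
  - {name: enamine, smarts: "[CX3]=[CX3][NX3]"}
  - {name: enol, smarts: "[CX3]=[CX3][OX2H]"}
  - {name: enol ether, smarts: "[CX3]=[CX3][OX2][#6]"}
  - {name: alcohol, smarts: "[CX4][OX2H]"}
  - {name: primary alcohol, smarts: "[CX4H2][OX2H]"}
  - {name: secondary alcohol, smarts: "[CX4H1]([#6])[OX2H]"}
  - {name: tertiary alcohol, smarts: "[CX4]([#6])([#6])([#6])[OX2H]"}
  - {name: 1_2-diol, smarts: "[OX2H][CX4][CX4][OX2H]"}
  - {name: phenol, smarts: "[c][OX2H]"}
  - {name: ether, smarts: "[OX2]([#6;!$([CX3]=[OX1])])[#6;!$([CX3]=[OX1])]"}
  - {name: dialkyl ether, smarts: "[CX4][OX2][CX4]"}
  - {name: alkyl aryl ether, smarts: "[c][OX2][CX4]"}
  - {name: diaryl ether, smarts: "[c][OX2][c]"}
  - {name: peroxide, smarts: "[#6][OX2][OX2][#6]"}
  - {name: hydroperoxide, smarts: "[#6][OX2][OX2H]"}
  - {name: acetal, smarts: "[CX4]([OX2][#6])[OX2][#6]"}
  - {name: hemiacetal, smarts: "[CX4]([OX2H])[OX2][#6]"}
  - {name: thiol, smarts: "[#6][SX2H]"}
  - {name: thioether, smarts: "[#6][SX2][#6]"}
  - {name: disulfide, smarts: "[#6][SX2][SX2][#6]"}
  - {name: primary amine, smarts: "[NX3H2][#6;!$([CX3]=[OX1,SX1,NX2])]"}
  - {name: secondary amine, smarts: "[NX3H1]([#6;!$([CX3]=[OX1,SX1,NX2])])[#6;!$([CX3]=[OX1,SX1,NX2])]"}
  - {name: tertiary amine, smarts: "[NX3]([#6;!$([CX3]=[OX1,SX1,NX2])])([#6;!$([CX3]=[OX1,SX1,NX2])])[#6;!$([CX3]=[OX1,SX1,NX2])]"}
  - {name: quaternary ammonium, smarts: "[NX4+]"}
  - {name: aromatic amine, smarts: "[NX3][c]"}
  - {name: hydroxylamine, smarts: "[NX3][OX2H]"}
  - {name: hydrazine, smarts: "[NX3][NX3]"}
  - {name: azo, smarts: "[#6][NX2]=[NX2][#6]"}
  - {name: azide, smarts: "[NX2]=[NX2+]=[NX1-]"}
  - {name: nitrile, smarts: "[CX2]#[NX1]"}
  - {name: isocyanate, smarts: "[NX2]=[CX2]=[OX1]"}
  - {name: isothiocyanate, smarts: "[NX2]=[CX2]=[SX1]"}
  - {name: thiocyanate, smarts: "[SX2][CX2]#[NX1]"}
  - {name: nitro, smarts: "[$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"}
  - {name: nitroso, smarts: "[#6][NX2]=[OX1]"}
  - {name: nitrate ester, smarts: "[#6][OX2][NX3+](=[OX1])[OX1-]"}
  - {name: carboxylic acid, smarts: "[CX3](=[OX1])[OX2H]"}
  - {name: carboxylate, smarts: "[CX3](=[OX1])[OX1-]"}
  - {name: ester, smarts: "[CX3](=[OX1])[OX2][#6]"}
  - {name: lactone, smarts: "[CX3;R](=[OX1])[OX2;R]"}
  - {name: amide, smarts: "[CX3](=[OX1])[NX3]"}
  - {name: primary amide, smarts: "[CX3](=[OX1])[NX3H2]"}
  - {name: secondary amide, smarts: "[CX3](=[OX1])[NX3H1][#6]"}
  - {name: tertiary amide, smarts: "[CX3](=[OX1])[NX3]([#6])[#6]"}
  - {name: lactam, smarts: "[CX3;R](=[OX1])[NX3;R]"}
  - {name: imide, smarts: "[NX3]([CX3]=[OX1])[CX3]=[OX1]"}
  - {name: urea, smarts: "[NX3][CX3](=[OX1])[NX3]"}
  - {name: carbamate, smarts: "[NX3][CX3](=[OX1])[OX2][#6]"}
  - {name: guanidine, smarts: "[NX3][CX3](=[NX2])[NX3]"}
  - {name: amidine, smarts: "[NX3][CX3]=[NX2]"}
  - {name: thioamide, smarts: "[CX3](=[SX1])[NX3]"}
  - {name: thiourea, smarts: "[NX3][CX3](=[SX1])[NX3]"}
  - {name: carbonate, smarts: "[OX2][CX3](=[OX1])[OX2]"}
  - {name: acyl halide, smarts: "[CX3](=[OX1])[F,Cl,Br,I]"}
  - {name: anhydride, smarts: "[CX3](=[OX1])[OX2][CX3]=[OX1]"}
  - {name: sulfonic acid, smarts: "[SX4](=[OX1])(=[OX1])[OX2H]"}
  - {name: sulfonate, smarts: "[SX4](=[OX1])(=[OX1])[OX1-]"}
  - {name: sulfonic ester, smarts: "[SX4](=[OX1])(=[OX1])[OX2][#6]"}
  - {name: sulfonamide, smarts: "[SX4](=[OX1])(=[OX1])[NX3]"}
  - {name: sulfone, smarts: "[#6][SX4](=[OX1])(=[OX1])[#6]"}
  - {name: sulfoxide, smarts: "[#6][SX3](=[OX1])[#6]"}
  - {name: sulfate ester, smarts: "[#6][OX2][SX4](=[OX1])(=[OX1])"}
  - {name: phosphate, smarts: "[PX4](=[OX1])([OX2,OX1-])([OX2,OX1-])[OX2,OX1-]"}
  - {name: phosphonate, smarts: "[PX4](=[OX1])([#6])([OX2,OX1-])[OX2,OX1-]"}
  - {name: fluoro, smarts: "[#6][F]"}
  - {name: chloro, smarts: "[#6][Cl]"}
  - {name: bromo, smarts: "[#6][Br]"}
  - {name: iodo, smarts: "[#6][I]"}
  - {name: trifluoromethyl, smarts: "[CX4](F)(F)F"}
  - {name: aryl halide, smarts: "[c][F,Cl,Br,I]"}
  - {name: aromatic ring, smarts: "[aR]~[aR]~[aR]"}
  - {name: benzene ring, smarts: "c1ccccc1"}
  - {name: aromatic heterocycle, smarts: "[a;!c]"}
  - {name: heterocycle, smarts: "[!#6;!#1;R]"}
  - {name: alkene, smarts: "[CX3]=[CX3]"}
  - {name: alkyne, smarts: "[CX2]#[CX2]"}
  - {name: alkane, smarts: "[CX4;!$([CX4][!#6;!#1])]"}
  - {name: methyl, smarts: "[CX4H3]"}
  - {name: michael acceptor, smarts: "[CX3]=[CX3][CX3]=[OX1]"}
  - {name: conjugated diene, smarts: "[CX3]=[CX3][CX3]=[CX3]"}
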