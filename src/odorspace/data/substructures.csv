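# Substructure / functional-group catalog: name,SMARTS (one flag column per row).
# A flag is 1 iff the pattern matches the molecule at least once.
# Aromaticity follows RDKit's default perception model.
# "long_unbranched_chain" approximates a >=8-atom contiguous acyclic carbon
# chain with no branching (each chain atom has at most two carbon neighbours,
# sp3 or sp2); "bicyclic" marks atoms shared by two SSSR rings (fused or
# bridged ring systems).
name,smarts
"carbonyl","[CX3]=[OX1]"
"ester","[CX3](=[OX1])[OX2][#6]"
"aldehyde","[CX3H1]=[OX1]"
"ketone","[#6][CX3](=[OX1])[#6]"
"alcohol","[CX4][OX2H]"
"phenol","[c][OX2H]"
"carboxylic_acid","[CX3](=[OX1])[OX2H]"
"aliphatic_amine","[NX3;!$(NC=O);!$(N[a]);!$(N=*)]"
"aromatic_amine","[NX3;!$(NC=O)][a]"
"thiol","[SX2H]"
"sulfide","[SX2]([#6])[#6]"
"allylic_group","[CX4;H1,H2,H3][CX3]=[CX3]"
"bicyclic","[R2]"
"unsaturated_ring","[$([aR]),$([#6R]=[#6R])]"
"aryl_methyl","[CH3][c]"
"furan","c1ccoc1"
"long_unbranched_chain","[#6;!R;H1,H2,H3;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2;!$([#6](~[#6])(~[#6])~[#6])]~[#6;!R;H1,H2,H3;!$([#6](~[#6])(~[#6])~[#6])]"
"lactone","[C;R](=[OX1])[O;R]"
"amide","[NX3][CX3]=[OX1]"
"nitrile","[NX1]#[CX2]"
"nitro","[$([NX3](=O)=O),$([NX3+](=O)[O-])]"
"aliphatic_ether","[CX4][OX2][CX4]"
"aryl_ether","[c][OX2][#6]"
"alkene","[CX3]=[CX3]"
"alkyne","[CX2]#[CX2]"
"terminal_alkene","[CX3H2]=[CX3]"
"benzene","c1ccccc1"
"pyridine","c1ccncc1"
"pyrrole","[nH]1cccc1"
"thiophene","c1ccsc1"
"pyrazine","c1cnccn1"
"oxazole","c1ocnc1"
"thiazole","c1scnc1"
"indole","c1ccc2c(c1)cc[nH]2"
"imine","[CX3]=[NX2]"
"epoxide","C1OC1"
"acetal","[CX4]([OX2][#6])[OX2][#6]"
"anhydride","[CX3](=[OX1])[OX2][CX3]=[OX1]"
"acyl_halide","[CX3](=[OX1])[F,Cl,Br,I]"
"sulfoxide","[#16X3]=[OX1]"
"sulfone","[#16X4](=[OX1])=[OX1]"
"disulfide","[SX2][SX2]"
"thioester","[SX2][CX3]=[OX1]"
"isothiocyanate","[NX2]=C=[SX1]"
"primary_amine","[NX3H2][CX4]"
"secondary_amine","[NX3H1]([CX4])[CX4]"
"tertiary_amine","[NX3]([CX4])([CX4])[CX4]"
"primary_alcohol","[CX4H2][OX2H]"
"secondary_alcohol","[CX4H1]([#6])[OX2H]"
"tertiary_alcohol","[CX4]([#6])([#6])([#6])[OX2H]"
"fluoro","[F]"
"chloro","[Cl]"
"bromo","[Br]"
"iodo","[I]"
"enol_ether","[OX2][CX3]=[CX3]"
"formate","[CX3H1](=[OX1])[OX2][#6]"
"acetate_ester","[CH3][CX3](=[OX1])[OX2][#6]"
"methyl_ketone","[CH3][CX3](=[OX1])[#6]"
"gem_dimethyl","[CX4]([CH3])([CH3])[#6]"
"isopropyl","[CX4H1]([CH3])[CH3]"
"isopropenyl","[CX3](=[CX3H2])[CH3]"
"conjugated_enone","[CX3]=[CX3][CX3]=[OX1]"
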