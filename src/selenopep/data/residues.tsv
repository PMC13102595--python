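# Default per-residue constants for Sec-aware peptide physicochemistry.
#
# Masses: average residue masses (free amino acid minus one water), standard
# atomic weights. Sec (U) avg_mass is a calibrated value (see docs/methods.md);
# the atomic-composition value for C3H5NOSe is 150.05 Da.
# pKa set: Solomon textbook values for canonical side chains and termini;
# Sec side-chain pKa 5.2 (selenol, ionized form -1).
# Hydrophobicity: Wimley-White whole-residue octanol scale (water -> octanol
# transfer free energy, kcal/mol; larger = more polar-soluble), charged form
# for His; Sec value calibrated (see docs/methods.md).
#meta	n_term_pka	9.6
#meta	c_term_pka	2.4
#meta	water_mass	18.0153
#meta	terminus_hydrophobicity	7.90
code	name	avg_mass	side_chain_pka	charge_when_ionized	hydrophobicity	residue_class
A	Alanine	71.0788			0.50	hydrophobic
R	Arginine	156.1875	12.5	+1	1.81	cationic
N	Asparagine	114.1038			0.85	polar
D	Aspartate	115.0886	3.9	-1	3.64	anionic
C	Cysteine	103.1388	8.3	-1	-0.02	polar
E	Glutamate	129.1155	4.3	-1	3.63	anionic
Q	Glutamine	128.1307			0.77	polar
G	Glycine	57.0519			1.15	special
H	Histidine	137.1411	6.0	+1	2.33	cationic
I	Isoleucine	113.1594			-1.12	hydrophobic
L	Leucine	113.1594			-1.25	hydrophobic
K	Lysine	128.1741	10.5	+1	2.80	cationic
M	Methionine	131.1926			-0.67	hydrophobic
F	Phenylalanine	147.1766			-1.71	hydrophobic
P	Proline	97.1167			0.14	special
S	Serine	87.0782			0.46	polar
T	Threonine	101.1051			0.25	polar
W	Tryptophan	186.2132			-2.09	hydrophobic
Y	Tyrosine	163.1760	10.1	-1	-0.71	polar
V	Valine	99.1326			-0.46	hydrophobic
U	Selenocysteine	150.42	5.2	-1	3.20	special
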