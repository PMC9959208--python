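"""Shared constant tables: residue masses, hydropathy, codon usage.

Residue masses are the standard monoisotopic / average masses of amino-acid
residues (i.e. the amino acid minus one water). They are frozen here rather
than taken from a mass-spec library so that the mass module stays an
independent implementation of the additive peptide-mass formula; the test
suite cross-checks every value against atomic-composition summation.
"""

from __future__ import annotations

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.007276
# loss of one H per cysteine on disulfide formation
DISULFIDE_MONO = 2 * 1.007825
DISULFIDE_AVG = 2 * 1.00794
# C-terminal -OH -> -NH2 (amidation): -O -H +N +2H
AMIDATION_MONO = 0.984016
AMIDATION_AVG = 0.98476

MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9,
    "A": 1.8, "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3,
    "P": -1.6, "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5,
    "K": -3.9, "R": -4.5,
}

# residues counted as "small" at the -1/-3 positions of a signal-peptidase site
SMALL_RESIDUES = frozenset("AGSCT")

# standard genetic code, coding strand codons -> amino acid ('*' = stop)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] = SYNONYMOUS[_aa] + (_codon,)
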