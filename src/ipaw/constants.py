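"""Monoisotopic mass constants used throughout the package.

All masses in Da. Residue masses are the standard monoisotopic masses of
amino acid residues (i.e. the amino acid minus water, as incorporated in a
peptide chain).
"""

WATER = 18.010565
PROTON = 1.007276

# common modification deltas
TMT10 = 229.162932
CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915
DEAMIDATION = 0.984016

# monoisotopic residue masses for the 20 standard amino acids
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

STANDARD_RESIDUES = frozenset(RESIDUE_MASSES)

# TMT 10-plex reporter ion m/z values (vendor monoisotopic, singly charged)
TMT10_REPORTER_MZ = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.138180,
}
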