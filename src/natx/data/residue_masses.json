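{
  "version": "1.0",
  "comment": "Standard amino-acid residue masses (Da). Average values use IUPAC standard atomic weights; monoisotopic values use the principal isotope masses.",
  "water_average": 18.01528,
  "water_monoisotopic": 18.0105646,
  "disulfide_average": 2.01588,
  "disulfide_monoisotopic": 2.0156500,
  "amidation_average": -0.98476,
  "amidation_monoisotopic": -0.9840156,
  "average": {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132
  },
  "monoisotopic": {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406, "N": 114.04293,
    "D": 115.02694, "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931
  }
}
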