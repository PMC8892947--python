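{
 "name": "synthetic-early-library",
 "alphabet": "ADEGILPSTV",
 "positions": [
  {
   "position": 1,
   "wild_type": "G",
   "allowed": "APST",
   "fixed": false,
   "codon": "NCA"
  },
  {
   "position": 2,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 3,
   "wild_type": "D",
   "allowed": "ADGV",
   "fixed": false,
   "codon": "GNC"
  },
  {
   "position": 4,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 5,
   "wild_type": "E",
   "allowed": "AEGV",
   "fixed": false,
   "codon": "GNA"
  },
  {
   "position": 6,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 7,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 8,
   "wild_type": "L",
   "allowed": "L",
   "fixed": true,
   "codon": "CTA"
  },
  {
   "position": 9,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  },
  {
   "position": 10,
   "wild_type": "T",
   "allowed": "T",
   "fixed": true,
   "codon": "ACA"
  },
  {
   "position": 11,
   "wild_type": "G",
   "allowed": "DEGV",
   "fixed": false,
   "codon": "GDK"
  },
  {
   "position": 12,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 13,
   "wild_type": "D",
   "allowed": "D",
   "fixed": true,
   "codon": "GAC"
  },
  {
   "position": 14,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 15,
   "wild_type": "E",
   "allowed": "APST",
   "fixed": false,
   "codon": "NCA"
  },
  {
   "position": 16,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 17,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 18,
   "wild_type": "L",
   "allowed": "ADGV",
   "fixed": false,
   "codon": "GNC"
  },
  {
   "position": 19,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  },
  {
   "position": 20,
   "wild_type": "T",
   "allowed": "T",
   "fixed": true,
   "codon": "ACA"
  },
  {
   "position": 21,
   "wild_type": "G",
   "allowed": "G",
   "fixed": true,
   "codon": "GGA"
  },
  {
   "position": 22,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 23,
   "wild_type": "D",
   "allowed": "D",
   "fixed": true,
   "codon": "GAC"
  },
  {
   "position": 24,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 25,
   "wild_type": "E",
   "allowed": "E",
   "fixed": true,
   "codon": "GAA"
  },
  {
   "position": 26,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 27,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 28,
   "wild_type": "L",
   "allowed": "AEGV",
   "fixed": false,
   "codon": "GNA"
  },
  {
   "position": 29,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  },
  {
   "position": 30,
   "wild_type": "T",
   "allowed": "T",
   "fixed": true,
   "codon": "ACA"
  },
  {
   "position": 31,
   "wild_type": "G",
   "allowed": "G",
   "fixed": true,
   "codon": "GGA"
  },
  {
   "position": 32,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 33,
   "wild_type": "D",
   "allowed": "DEGV",
   "fixed": false,
   "codon": "GDK"
  },
  {
   "position": 34,
   "wild_type": "V",
   "allowed": "APST",
   "fixed": false,
   "codon": "NCA"
  },
  {
   "position": 35,
   "wild_type": "E",
   "allowed": "E",
   "fixed": true,
   "codon": "GAA"
  },
  {
   "position": 36,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 37,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 38,
   "wild_type": "L",
   "allowed": "ADGV",
   "fixed": false,
   "codon": "GNC"
  },
  {
   "position": 39,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  },
  {
   "position": 40,
   "wild_type": "T",
   "allowed": "AEGV",
   "fixed": false,
   "codon": "GNA"
  },
  {
   "position": 41,
   "wild_type": "G",
   "allowed": "DEGV",
   "fixed": false,
   "codon": "GDK"
  },
  {
   "position": 42,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 43,
   "wild_type": "D",
   "allowed": "ILV",
   "fixed": false,
   "codon": "DTA"
  },
  {
   "position": 44,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 45,
   "wild_type": "E",
   "allowed": "DGV",
   "fixed": false,
   "codon": "GDC"
  },
  {
   "position": 46,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 47,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 48,
   "wild_type": "L",
   "allowed": "L",
   "fixed": true,
   "codon": "CTA"
  },
  {
   "position": 49,
   "wild_type": "P",
   "allowed": "ILV",
   "fixed": false,
   "codon": "DTA"
  },
  {
   "position": 50,
   "wild_type": "T",
   "allowed": "APT",
   "fixed": false,
   "codon": "VCA"
  },
  {
   "position": 51,
   "wild_type": "G",
   "allowed": "G",
   "fixed": true,
   "codon": "GGA"
  },
  {
   "position": 52,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 53,
   "wild_type": "D",
   "allowed": "D",
   "fixed": true,
   "codon": "GAC"
  },
  {
   "position": 54,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 55,
   "wild_type": "E",
   "allowed": "E",
   "fixed": true,
   "codon": "GAA"
  },
  {
   "position": 56,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 57,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 58,
   "wild_type": "L",
   "allowed": "AEG",
   "fixed": false,
   "codon": "GVA"
  },
  {
   "position": 59,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  },
  {
   "position": 60,
   "wild_type": "T",
   "allowed": "T",
   "fixed": true,
   "codon": "ACA"
  },
  {
   "position": 61,
   "wild_type": "G",
   "allowed": "G",
   "fixed": true,
   "codon": "GGA"
  },
  {
   "position": 62,
   "wild_type": "A",
   "allowed": "A",
   "fixed": true,
   "codon": "GCA"
  },
  {
   "position": 63,
   "wild_type": "D",
   "allowed": "D",
   "fixed": true,
   "codon": "GAC"
  },
  {
   "position": 64,
   "wild_type": "V",
   "allowed": "V",
   "fixed": true,
   "codon": "GTA"
  },
  {
   "position": 65,
   "wild_type": "E",
   "allowed": "DEG",
   "fixed": false,
   "codon": "GRK"
  },
  {
   "position": 66,
   "wild_type": "S",
   "allowed": "S",
   "fixed": true,
   "codon": "AGC"
  },
  {
   "position": 67,
   "wild_type": "I",
   "allowed": "I",
   "fixed": true,
   "codon": "ATA"
  },
  {
   "position": 68,
   "wild_type": "L",
   "allowed": "L",
   "fixed": true,
   "codon": "CTA"
  },
  {
   "position": 69,
   "wild_type": "P",
   "allowed": "P",
   "fixed": true,
   "codon": "CCA"
  }
 ]
}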