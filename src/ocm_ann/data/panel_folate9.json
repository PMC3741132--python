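[
  {"name": "MTHFR_C677T", "rsid": "rs1801133", "wild": "CC", "het": "CT", "mut": "TT"},
  {"name": "MTHFR_A1298C", "rsid": "rs1801131", "wild": "AA", "het": "AC", "mut": "CC"},
  {"name": "TYMS_28bp", "rsid": "rs34743033", "wild": "2R2R", "het": "2R3R", "mut": "3R3R"},
  {"name": "TYMS_6bp", "rsid": "rs34489327", "wild": "+/+", "het": "+/-", "mut": "-/-"},
  {"name": "MTRR_A66G", "rsid": "rs1801394", "wild": "AA", "het": "AG", "mut": "GG"},
  {"name": "MTR_A2756G", "rsid": "rs1805087", "wild": "AA", "het": "AG", "mut": "GG"},
  {"name": "RFC1_A80G", "rsid": "rs1051266", "wild": "AA", "het": "AG", "mut": "GG"},
  {"name": "DNMT3B_149CT", "rsid": "rs2424913", "wild": "CC", "het": "CT", "mut": "TT"},
  {"name": "DNMT3B_579GT", "rsid": "rs1569686", "wild": "GG", "het": "GT", "mut": "TT"}
]
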