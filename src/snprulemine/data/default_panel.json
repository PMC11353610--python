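[
  {"gene": "IL-4",    "rsid": "rs2243250", "major": "C", "minor": "T"},
  {"gene": "IL-4R",   "rsid": "rs1801275", "major": "A", "minor": "G"},
  {"gene": "IL-6",    "rsid": "rs1800795", "major": "G", "minor": "C"},
  {"gene": "IL-10",   "rsid": "rs1800896", "major": "A", "minor": "G"},
  {"gene": "IL-10",   "rsid": "rs1800872", "major": "C", "minor": "A"},
  {"gene": "IL-10RB", "rsid": "rs2834167", "major": "A", "minor": "G"},
  {"gene": "IL-13",   "rsid": "rs1800925", "major": "C", "minor": "T"},
  {"gene": "IL-18",   "rsid": "rs187238",  "major": "G", "minor": "C"},
  {"gene": "IFNG",    "rsid": "rs2430561", "major": "T", "minor": "A"},
  {"gene": "IFNGR2",  "rsid": "rs2834213", "major": "A", "minor": "G"},
  {"gene": "CD23",    "rsid": "rs2228137", "major": "C", "minor": "T"},
  {"gene": "Klotho",  "rsid": "rs577912",  "major": "C", "minor": "A"},
  {"gene": "Klotho",  "rsid": "rs564481",  "major": "C", "minor": "T"}
]
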