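# Default simulation config: study-sized case-control cohort (308 / 205)
# at the observed per-group minor-allele frequencies, with three planted
# multi-locus genotype clusters at the confidence/support of representative
# mined rules.  Frequencies are minor-allele fractions per group.
n_cases: 308
n_controls: 205
seed: 0
freqs:
  rs2243250: {control: 0.1146, case: 0.0909}   # IL-4, minor T
  rs1801275: {control: 0.1951, case: 0.1769}   # IL-4R, minor G
  rs1800795: {control: 0.3220, case: 0.2143}   # IL-6, minor C
  rs1800896: {control: 0.3683, case: 0.3084}   # IL-10, minor G
  rs1800872: {control: 0.2878, case: 0.3117}   # IL-10, minor A
  rs2834167: {control: 0.2659, case: 0.5373}   # IL-10RB, minor G
  rs1800925: {control: 0.2829, case: 0.1851}   # IL-13, minor T
  rs187238:  {control: 0.3073, case: 0.2581}   # IL-18, minor C
  rs2430561: {control: 0.4878, case: 0.4659}   # IFNG, minor A
  rs2834213: {control: 0.3927, case: 0.3458}   # IFNGR2, minor G
  rs2228137: {control: 0.2098, case: 0.2922}   # CD23, minor T
  rs577912:  {control: 0.1317, case: 0.1477}   # Klotho, minor A
  rs564481:  {control: 0.3537, case: 0.6104}   # Klotho, minor T
clusters:
  - label: cluster_A
    pattern: {rs2834213: "A/G", rs2834167: "G/G"}
    confidence: 0.934
    support: 0.111
  - label: cluster_B
    pattern: {rs2834167: "G/G", rs2243250: "C/C"}
    confidence: 0.901
    support: 0.160
  - label: cluster_C
    pattern: {rs564481: "T/T", rs1800795: "G/G", rs1800925: "C/C"}
    confidence: 0.941
    support: 0.125
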