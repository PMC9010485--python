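# Default fine-mapping marker panel for the Ga2 interval.
# Physical positions (Mb, locus-local coordinates) are a fixture: only the
# printed interval sizes (M5-M8 = 1.21 Mb, M3-M8 = 1.7 Mb) are anchored;
# everything else is a plausible ladder.  Genetic positions are derived
# with a configurable local recombination rate (cM per Mb); the default
# 0.2 cM/Mb is a fixture assumption justified by the paucity of observed
# recombinants in 16,544 screened meioses, not a measured value.
rate_cM_per_Mb: 0.2
determinant_Mb: 3.4
markers:
  - {name: M1, Mb: 0.0}
  - {name: M2, Mb: 1.2}
  - {name: M3, Mb: 2.31}
  - {name: M4, Mb: 2.55}
  - {name: M5, Mb: 2.8}
  - {name: M6, Mb: 3.3}
  - {name: M7, Mb: 3.7}
  - {name: M8, Mb: 4.01}
  - {name: M9, Mb: 4.6}
  - {name: M10, Mb: 5.2}
  - {name: M11, Mb: 5.9}
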