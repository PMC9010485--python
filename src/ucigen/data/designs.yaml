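# Executable catalog of the named genetic experiments.
# Pedigree steps build named populations from founder genotypes; the
# readout turns a population (or a single cross) into an expected outcome.
# Founders are defined in ucigen.lines; designs are data, not code.
designs:
  - id: D1
    description: Male-determinant dominance; (W22 x 511L) F1 pollen onto 511L silks.
    n_reported: null
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
    readout:
      kind: donor_seedset
      population: F1
      tester: "511L"
      classes: [full, low]

  - id: D2
    description: Single-gene test of the male determinant; W22 x (W22 x 511L) BC1F1 plants as pollen donors onto 511L.
    n_reported: 240
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1m, cross: {mother: W22, father: F1}}
    readout:
      kind: donor_seedset
      population: BC1F1m
      tester: "511L"
      classes: [full, low]

  - id: D3
    description: Gametophytic test of the male determinant; 511L x (W22 x 511L) BC1F2 plants as pollen donors onto 511L.
    n_reported: 105
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1h, cross: {mother: "511L", father: F1}}
      - {name: BC1F2, self: BC1F1h}
    readout:
      kind: donor_seedset
      population: BC1F2
      tester: "511L"
      classes: [full, low]

  - id: D4
    description: Marker transmission in the 511L x (W22 x 511L) BC1F1; flanking markers M1/M9 expected all-511L.
    n_reported: 88
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1h, cross: {mother: "511L", father: F1}}
    readout:
      kind: marker_transmission
      population: BC1F1h
      markers: [M1, M9]
      classes: [all-donor, recombinant]

  - id: D5
    description: Female-determinant recessivity; (W22 x 511L) F1 silks pollinated with W22.
    n_reported: 5
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
    readout:
      kind: silk_seedset
      population: F1
      tester: W22
      classes: [full, low]

  - id: D6
    description: Single-gene test of the female determinant; (W22 x 511L) x 511L BC1F1 silks pollinated with W22.
    n_reported: 220
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1f, cross: {mother: F1, father: "511L"}}
    readout:
      kind: silk_seedset
      population: BC1F1f
      tester: W22
      classes: [full, low]

  - id: D7
    description: Sporophytic test of the female determinant; (W22 x 511L) x W22 BC1F2 silks pollinated with W22.
    n_reported: 188
    reported_ratio: "8:1"
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1w, cross: {mother: F1, father: W22}}
      - {name: BC1F2w, self: BC1F1w}
    readout:
      kind: silk_seedset
      population: BC1F2w
      tester: W22
      classes: [full, none]

  - id: D8
    description: Genotype check of the (W22 x 511L) x W22 BC1F1 with flanking markers.
    n_reported: 88
    pedigree:
      - {name: F1, cross: {mother: W22, father: "511L"}}
      - {name: BC1F1w, cross: {mother: F1, father: W22}}
    readout:
      kind: genotype_ratio
      population: BC1F1w
      locus: Ga2
      classes: ["S/wt", "wt/wt"]

  - id: D9
    description: Transgenic validation of the male determinant; 511L silks vs hemizygous P-transgene and control pollen.
    n_reported: null
    pedigree: []
    readout:
      kind: compatibility_matrix
      females: ["511L"]
      donors: [MP-hemi, B104]

  - id: D10
    description: Transgenic validation of the female determinant; homozygous F-transgene mother, sequential ZYM1 then Mo17 pollen.
    n_reported: null
    pedigree: []
    readout:
      kind: ear_composition
      mother: CS-hom
      pool:
        application: sequential
        components:
          - {donor: ZYM1, proportion: 0.5}
          - {donor: Mo17, proportion: 0.5}
      classes: [purple, yellow]

  - id: D10h
    description: Hemizygous F-transgene mother with the same sequential pollen; mixed-colour ear expected.
    n_reported: null
    pedigree: []
    readout:
      kind: ear_composition
      mother: CS-hemi
      pool:
        application: sequential
        components:
          - {donor: ZYM1, proportion: 0.5}
          - {donor: Mo17, proportion: 0.5}
      classes: [purple, yellow]

  - id: D11
    description: Field isolation test; S-haplotype NIL hybrid pollinated with a ZYM1 + self pollen mixture.
    n_reported: null
    pedigree: []
    readout:
      kind: ear_composition
      mother: NILhybrid-Ga2S
      pool:
        application: mixed
        components:
          - {donor: ZYM1, proportion: 0.5}
          - {donor: NILhybrid-Ga2S, proportion: 0.5}
      classes: [purple, yellow]

  - id: D11g
    description: Field isolation control; ga2 NIL hybrid with the same pollen mixture accepts both components.
    n_reported: null
    pedigree: []
    readout:
      kind: ear_composition
      mother: NILhybrid-ga2
      pool:
        application: mixed
        components:
          - {donor: ZYM1, proportion: 0.5}
          - {donor: NILhybrid-Ga2S, proportion: 0.5}
      classes: [purple, yellow]

  - id: D12
    description: Ga1 + Ga2 pyramiding compatibility matrix.
    n_reported: null
    pedigree: []
    readout:
      kind: compatibility_matrix
      females: [Ga1Ga2]
      donors:
        - Ga1Ga2
        - SDGa25
        - "511L"
        - {mix: [SDGa25, "511L"]}
        - Zheng58

  - id: D13
    description: Herbicide-resistance transmission; homozygous F-transgene mother crossed to Mo17.
    n_reported: null
    pedigree: []
    readout:
      kind: progeny_fraction
      mother: CS-hom
      pool:
        application: mixed
        components:
          - {donor: Mo17, proportion: 1.0}
      classifier: transgene
      classes: [resistant, susceptible]
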