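# Packaged retrospective cohort: 12 confirmed 21-OHD cases, 4 carriers,
# and 57 variant-free samples (the traditional-screen false positives and
# healthy controls).  Structural classes are named by junction bin; "tnx"
# junctions live in the downstream-flank bin namespace (TNXA/TNXB).
barcode_seed: 7
negatives: 57
cases:
  - id: case01
    status: AFFECTED
    hap_a: {variants: ["c.518T>A"]}
    hap_b: {variants: ["c.844G>T", "c.923dup", "c.955C>T", "c.1069C>T"]}
  - id: case02
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.518T>A"]}
  - id: case03
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.740del", "c.*1316C>T"]}
  - id: case04
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.518T>A"]}
  - id: case05
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.518T>A", "c.*1215C>T", "c.*1316C>T", "c.*1351G>C"]}
  - id: case06
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.293-13C>G"]}
  - id: case07
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.518T>A"]}
  - id: case08
    status: AFFECTED
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {variants: ["c.293-13C>G"]}
  - id: case09
    status: AFFECTED
    hap_a: {variants: ["c.518T>A"]}
    hap_b: {variants: ["c.518T>A"]}
  - id: case10
    status: AFFECTED
    hap_a: {variants: ["c.92C>T"]}
    hap_b: {variants: ["c.92C>T"]}
  - id: case11
    status: AFFECTED
    hap_a: {structure: TNX_CHIMERA, bin: CH-1}
    hap_b: {structure: DEL_CHIMERA, bin: CH-8}
  - id: case12
    status: AFFECTED
    hap_a: {variants: ["c.518T>A"]}
    hap_b: {structure: DEL_CHIMERA, bin: CH-1}
  # carriers: one pathogenic allele; three carry a fusion duplication whose
  # extra fused copy leaves two intact functional copies
  - id: carrier30
    status: CARRIER
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {}
  - id: carrier41
    status: CARRIER
    hap_a: {variants: ["c.518T>A"]}
    hap_b: {structure: DUP_FUSION, bin: CH-1, copies: 1}
  - id: carrier59
    status: CARRIER
    hap_a: {variants: ["c.293-13C>G"]}
    hap_b: {structure: DUP_FUSION, bin: CH-3, copies: 1}
  - id: carrier60
    status: CARRIER
    hap_a: {variants: ["c.92C>T"]}
    hap_b: {structure: DUP_FUSION, bin: CH-8, copies: 1}
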