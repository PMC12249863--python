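# S. cerevisiae Hsp104-DWB disaggregase, closed conformation.
# Structure file (not shipped): download 6N8T from the PDB.
structures:
  - id: 6N8T
    path: ../data/structures/6n8t.cif
scale: kd_normalized
cutoff: 9.0
k_max: 10.0
units:
  - name: COMPLEX A-F
    structure: 6N8T
    chains: [A, B, C, D, E, F]
  - name: CHAIN A
    structure: 6N8T
    chains: [A]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN B
    structure: 6N8T
    chains: [B]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN C
    structure: 6N8T
    chains: [C]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN D
    structure: 6N8T
    chains: [D]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN E
    structure: 6N8T
    chains: [E]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN F
    structure: 6N8T
    chains: [F]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
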