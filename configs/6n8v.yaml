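# S. cerevisiae Hsp104-DWB disaggregase, open conformation.
# Structure file (not shipped): download 6N8V from the PDB.
structures:
  - id: 6N8V
    path: ../data/structures/6n8v.cif
scale: kd_normalized
cutoff: 9.0
k_max: 10.0
units:
  - name: COMPLEX A-F
    structure: 6N8V
    chains: [A, B, C, D, E, F]
  - name: CHAIN A
    structure: 6N8V
    chains: [A]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN B
    structure: 6N8V
    chains: [B]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN C
    structure: 6N8V
    chains: [C]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN D
    structure: 6N8V
    chains: [D]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN E
    structure: 6N8V
    chains: [E]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
  - name: CHAIN F
    structure: 6N8V
    chains: [F]
    contexts: [individual, in_complex]
    parent: COMPLEX A-F
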