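# Hsp104 + casein complex: full unit decomposition.
# Structure file (not shipped): download 5VJH from the PDB, e.g.
#   curl -o data/structures/5vjh.cif https://files.rcsb.org/download/5VJH.cif
structures:
  - id: 5VJH
    path: ../data/structures/5vjh.cif
# Chain P (casein guest) is deposited without sequence (backbone + CB only)
# and is treated as poly-alanine.
polyalanine_chains:
  5VJH: [P]
scale: kd_normalized
cutoff: 9.0
k_max: 10.0
units:
  - name: CHAINS A-F + P
    structure: 5VJH
    chains: [A, B, C, D, E, F, P]
  - name: CHAINS A-F
    structure: 5VJH
    chains: [A, B, C, D, E, F]
  - name: CHAIN A
    structure: 5VJH
    chains: [A]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN B
    structure: 5VJH
    chains: [B]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN C
    structure: 5VJH
    chains: [C]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN D
    structure: 5VJH
    chains: [D]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN E
    structure: 5VJH
    chains: [E]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN F
    structure: 5VJH
    chains: [F]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN P
    structure: 5VJH
    chains: [P]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  # Pseudo-domains of chain A, delimited by local packing (config data,
  # not computed).
  - name: PD1 165-340
    structure: 5VJH
    selections: [{chain: A, start: 165, end: 340}]
  - name: PD2 344-557
    structure: 5VJH
    selections: [{chain: A, start: 344, end: 557}]
  - name: PD3 558-775
    structure: 5VJH
    selections: [{chain: A, start: 558, end: 775}]
  - name: PD4 776-884
    structure: 5VJH
    selections: [{chain: A, start: 776, end: 884}]
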