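# Human mitochondrial disaggregase (Skd3) + casein 14-mer.
# Structure file (not shipped): download 7TTR from the PDB.
structures:
  - id: 7TTR
    path: ../data/structures/7ttr.cif
# The casein substrate (chain P) is deposited without sequence; poly-alanine.
polyalanine_chains:
  7TTR: [P]
scale: kd_normalized
cutoff: 9.0
k_max: 10.0
units:
  - name: CHAINS A-F
    structure: 7TTR
    chains: [A, B, C, D, E, F]
  - name: CHAINS A-F + P
    structure: 7TTR
    chains: [A, B, C, D, E, F, P]
  - name: CHAIN A
    structure: 7TTR
    chains: [A]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN B
    structure: 7TTR
    chains: [B]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN C
    structure: 7TTR
    chains: [C]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN D
    structure: 7TTR
    chains: [D]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN E
    structure: 7TTR
    chains: [E]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN F
    structure: 7TTR
    chains: [F]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: CHAIN P
    structure: 7TTR
    chains: [P]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  # Pseudo-domains of chain C (no CATH assignment exists for this entry).
  - name: C-PD1 327-569
    structure: 7TTR
    selections: [{chain: C, start: 327, end: 569}]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: C-PD2 570-653
    structure: 7TTR
    selections: [{chain: C, start: 570, end: 653}]
    contexts: [individual, in_complex]
    parent: CHAINS A-F + P
  - name: C-PD3 338-569
    structure: 7TTR
    selections: [{chain: C, start: 338, end: 569}]
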