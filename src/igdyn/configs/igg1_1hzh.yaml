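# RECONSTRUCTED domain boundaries for a full-length human IgG1 crystal
# structure (e.g. 1HZH) in EU numbering.  These residue ranges are a
# documented reconstruction from standard IgG1 domain architecture
# (VH ~1-117, CH1 ~118-215, hinge ~216-230, CH2 ~231-340, CH3 ~341-447;
# VL ~1-107, CL ~108-214), NOT values taken from any specific analysis.
# Edit chain ids and ranges to match your structure file.
mode: antibody
beads:
  - id: 1
    label: Fc_CH3
    selections:
      - {chain: H, start: 341, end: 447}
      - {chain: K, start: 341, end: 447}
  - id: 2
    label: Fc_CH2
    selections:
      - {chain: H, start: 231, end: 340}
      - {chain: K, start: 231, end: 340}
  - id: 3
    label: Fab1_CH1_CL
    selections:
      - {chain: H, start: 118, end: 215}
      - {chain: L, start: 108, end: 214}
  - id: 4
    label: Fab1_VH_VL
    selections:
      - {chain: H, start: 1, end: 117}
      - {chain: L, start: 1, end: 107}
  - id: 5
    label: Fab2_CH1_CL
    selections:
      - {chain: K, start: 118, end: 215}
      - {chain: M, start: 108, end: 214}
  - id: 6
    label: Fab2_VH_VL
    selections:
      - {chain: K, start: 1, end: 117}
      - {chain: M, start: 1, end: 107}
fragments:
  hinge:
    - {chain: H, start: 216, end: 230}
    - {chain: K, start: 216, end: 230}
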