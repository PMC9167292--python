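# Domain configuration for the synthetic antibody layout produced by
# igdyn.synthetic_data: one chain per fragment (A: Fc, B: Fab1, C: Fab2),
# beads as residue ranges 1-100 / 101-200, hinge at A:500+, planted
# hydrogen-bond residues at 2001+ (donors) and 3001+ (acceptors).
mode: antibody
beads:
  - id: 1
    label: Fc_CH3
    selections: [{chain: A, start: 1, end: 100}]
  - id: 2
    label: Fc_CH2
    selections: [{chain: A, start: 101, end: 200}]
  - id: 3
    label: Fab1_CH1_CL
    selections: [{chain: B, start: 1, end: 100}]
  - id: 4
    label: Fab1_VH_VL
    selections: [{chain: B, start: 101, end: 200}]
  - id: 5
    label: Fab2_CH1_CL
    selections: [{chain: C, start: 1, end: 100}]
  - id: 6
    label: Fab2_VH_VL
    selections: [{chain: C, start: 101, end: 200}]
fragments:
  hinge: [{chain: A, start: 500, end: 599}]
  Fc:    [{chain: A, start: 2001, end: 3999}]
  Fab1:  [{chain: B, start: 2001, end: 3999}]
  Fab2:  [{chain: C, start: 2001, end: 3999}]
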