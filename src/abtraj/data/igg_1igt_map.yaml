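# Example domain map for an intact IgG2a (PDB entry 1IGT, author numbering).
#
# ASSUMPTIONS — read before trusting:
#   * Domain boundaries are approximate sequence-based splits of the light
#     (VL/CL) and heavy (VH/CH1/hinge linker/CH2/CH3) chains; refine against
#     the actual structure for production use.
#   * The chain hosting each anchor residue is NOT recorded in the analysis
#     this map mirrors; placing Asp31, Cys225 and Phe442 on heavy chain B and
#     Lys65 on heavy chain D is this package's documented assumption, not an
#     established fact.  Angle values depend on this choice.
fragments:
  - {label: VL_A,    chain: A, ranges: [[1, 108]]}
  - {label: CL_A,    chain: A, ranges: [[109, 214]]}
  - {label: VL_C,    chain: C, ranges: [[1, 108]]}
  - {label: CL_C,    chain: C, ranges: [[109, 214]]}
  - {label: VH_B,    chain: B, ranges: [[1, 113]]}
  - {label: CH1_B,   chain: B, ranges: [[114, 220]]}
  - {label: linker_B, chain: B, ranges: [[221, 237]]}
  - {label: CH2_B,   chain: B, ranges: [[238, 340]]}
  - {label: CH3_B,   chain: B, ranges: [[341, 444]]}
  - {label: VH_D,    chain: D, ranges: [[1, 113]]}
  - {label: CH1_D,   chain: D, ranges: [[114, 220]]}
  - {label: linker_D, chain: D, ranges: [[221, 237]]}
  - {label: CH2_D,   chain: D, ranges: [[238, 340]]}
  - {label: CH3_D,   chain: D, ranges: [[341, 444]]}
regions:
  fab_left: [VL_A, CL_A, VH_B, CH1_B]
  fab_right: [VL_C, CL_C, VH_D, CH1_D]
  fc: [CH2_B, CH3_B, CH2_D, CH3_D]
anchors:
  fab_left:  {chain: B, resid: 31,  atom_rule: CA, resname: ASP}
  fab_right: {chain: D, resid: 65,  atom_rule: CA, resname: LYS}
  hinge:     {chain: B, resid: 225, atom_rule: CA, resname: CYS}
  fc:        {chain: B, resid: 442, atom_rule: CA, resname: PHE}
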