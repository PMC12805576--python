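# Packaged CG bead chemotypes (MARTINI-3 style labels).
# size_class T/S/R fixes the vdW radius (0.191/0.230/0.264 nm) and the
# bead mass (36/54/72 Da) unless explicitly overridden per entry.
bead_types:
  P2:    {size_class: R}            # protein backbone
  SC3:   {size_class: S}            # proline side chain
  SP1:   {size_class: S}            # threonine side chain
  TP1:   {size_class: T}            # serine side chain / sugar N-acetyl
  TC4:   {size_class: T}            # His CB-CG; also ring-center virtual site
  TN6d:  {size_class: T}            # His imidazole (donor)
  TN5a:  {size_class: T}            # His imidazole (acceptor)
  SN6:   {size_class: S}            # sugar anomeric bead, free reducing end
  TC5:   {size_class: T}            # glycosylated N-acetylhexosamine anomeric
  TN6:   {size_class: T}            # glycosylated (non-HexNAc) anomeric
  SP4:   {size_class: S}            # sugar ring bead
  SN4ar: {size_class: S}            # threonine-glycan linkage bead
  TN4ar: {size_class: T}            # serine-glycan linkage bead
  Q4n:   {size_class: R, charge: -1}   # sulfate group
  SQ5n:  {size_class: S, charge: -1}   # sialic-acid carboxylate
  W:     {size_class: R}            # water bead (4 H2O)
  TQ5+:  {size_class: T, charge: 1}    # sodium cation bead
  TQ5-:  {size_class: T, charge: -1}   # chloride anion bead
# Interaction-group labels used by the nonbonded table.
groups:
  protein: [P2, SC3, SP1, TP1, TN6d, TN5a, SN4ar, TN4ar]
  glycan:  [SN6, TC5, TN6, SP4, TC4, Q4n, SQ5n]
  water:   [W]
  ion:     ["TQ5+", "TQ5-"]
# Lennard-Jones defaults: sigma by size-class pair (arithmetic mean of the
# per-class values below), one generic epsilon for every pair.
lj:
  sigma: {R: 0.47, S: 0.41, T: 0.34}
  epsilon_default: 2.3
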