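# Residue -> bead mapping templates.
#
# Protein residues follow the standard MARTINI 3 one-backbone-bead-per-residue
# convention with side-chain beads per standard templates.  The sugar
# templates are SYNTHETIC stand-ins written for this package: they keep the
# MARTINI 3 three-ring-bead + side-bead architecture, the published bead
# chemotypes (SN6/TC5 anomeric, Q4n sulfate, SQ5n carboxylate) and the strict
# 2/3/4 heavy atoms per T/S/R bead rule, but use a reduced heavy-atom
# complement; replace this file to map real chemistries.
#
# "optional" atoms may be absent from a structure (the anomeric hydroxyl
# oxygen is lost when the sugar becomes a glycosyl donor).  "ring" beads of a
# residue form one rigid group.
protein:
  GLY:
    beads:
      - {name: BB, type: P2, atoms: [N, CA, C, O]}
    intra_bonds: []
  PRO:
    beads:
      - {name: BB, type: P2, atoms: [N, CA, C, O]}
      - {name: SC1, type: SC3, atoms: [CB, CG, CD]}
    intra_bonds: [[BB, SC1]]
  SER:
    beads:
      - {name: BB, type: P2, atoms: [N, CA, C, O]}
      - {name: SC1, type: TP1, atoms: [CB, OG]}
    intra_bonds: [[BB, SC1]]
  THR:
    beads:
      - {name: BB, type: P2, atoms: [N, CA, C, O]}
      - {name: SC1, type: SP1, atoms: [CB, OG1, CG2]}
    intra_bonds: [[BB, SC1]]
  HIS:   # neutral (deprotonated imidazole) form
    beads:
      - {name: BB, type: P2, atoms: [N, CA, C, O]}
      - {name: SC1, type: TC4, atoms: [CB, CG]}
      - {name: SC2, type: TN6d, atoms: [ND1, CE1]}
      - {name: SC3, type: TN5a, atoms: [CD2, NE2]}
    intra_bonds: [[BB, SC1], [SC1, SC2], [SC1, SC3]]
sugars:
  GALNAC:
    beads:
      - {name: A, type: SN6, atoms: [C1, C2, O1], ring: true, optional: [O1]}
      - {name: B, type: SP4, atoms: [C3, C4, O3], ring: true}
      - {name: C, type: SP1, atoms: [C5, C6, O5], ring: true}
      - {name: NAC, type: TP1, atoms: [N2, C7]}
    intra_bonds: [[A, B], [B, C], [C, A], [A, NAC]]
    anomeric_bead: A
    anomeric_oh: O1
    hexnac: true
    acceptor_atom: O3
  GLCNAC:
    beads:
      - {name: A, type: SN6, atoms: [C1, C2, O1], ring: true, optional: [O1]}
      - {name: B, type: SP4, atoms: [C3, C4, O3], ring: true}
      - {name: C, type: SP1, atoms: [C5, C6, O5], ring: true}
      - {name: NAC, type: TP1, atoms: [N2, C7]}
    intra_bonds: [[A, B], [B, C], [C, A], [A, NAC]]
    anomeric_bead: A
    anomeric_oh: O1
    hexnac: true
    acceptor_atom: O3
  GAL:
    beads:
      - {name: A, type: SN6, atoms: [C1, C2, O1], ring: true, optional: [O1]}
      - {name: B, type: SP4, atoms: [C3, C4, O3], ring: true}
      - {name: C, type: SP1, atoms: [C5, C6, O5], ring: true}
    intra_bonds: [[A, B], [B, C], [C, A]]
    anomeric_bead: A
    anomeric_oh: O1
    hexnac: false
    acceptor_atom: O3
  GALS:   # 6-O-sulfated galactose
    beads:
      - {name: A, type: SN6, atoms: [C1, C2, O1], ring: true, optional: [O1]}
      - {name: B, type: SP4, atoms: [C3, C4, O3], ring: true}
      - {name: C, type: SP1, atoms: [C5, C6, O5], ring: true}
      - {name: S6, type: Q4n, atoms: [S6, OS1, OS2, OS3]}
    intra_bonds: [[A, B], [B, C], [C, A], [C, S6]]
    anomeric_bead: A
    anomeric_oh: O1
    hexnac: false
    acceptor_atom: O3
  NEU5AC:
    beads:
      - {name: A, type: SN6, atoms: [C2, C3, O2], ring: true, optional: [O2]}
      - {name: B, type: SP1, atoms: [C4, C5, O4], ring: true}
      - {name: C, type: SP4, atoms: [C6, C7, O6], ring: true}
      - {name: COO, type: SQ5n, atoms: [C1, O1A, O1B]}
      - {name: NAC, type: TP1, atoms: [N5, C10]}
    intra_bonds: [[A, B], [B, C], [C, A], [A, COO], [B, NAC]]
    anomeric_bead: A
    anomeric_oh: O2
    hexnac: false
    acceptor_atom: null
attachment:
  THR: {side_bead: SC1, link_type: SN4ar, link_atom: OG1}
  SER: {side_bead: SC1, link_type: TN4ar, link_atom: OG}
donor_retype:
  hexnac: TC5
  default: TN6
# Generic force constants used when bonded terms are first instantiated at
# mapping time (equilibrium values come from the mapped geometry; the
# inversion module replaces both from trajectory statistics).
bonded_defaults:
  bond: {k_b: 5000.0}
  angle: {k_theta: 25.0}
  dihedral: {k_phi: 1.5, n: 1, phi_s: 180.0}
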