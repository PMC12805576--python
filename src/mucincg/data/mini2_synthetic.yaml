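# SYNTHETIC composition table for the Mini2 MUC5B construct.
#
# The construct is a 30-amino-acid PTS-domain consensus glycopeptide carrying
# 18 O-glycans with a net charge of -13 e.  The published construct's exact
# sequence and per-site glycan identities live in supplementary material that
# is not distributed with this package, so the assignment below is a
# documented synthetic stand-in with the correct residue count, glycan count,
# serine/threonine linkage split and total charge.  Replace this file to use
# a measured composition.
#
# Sequence: 30 residues, PTS-rich, one neutral histidine near the C-terminus.
name: MINI2-MUC5B-SYNTHETIC
sequence: TTSPTGTSTPTSTGTTSPTGTSTPTGSTHG
# 18 glycosylation sites (1-based residue index) in N->C order with their
# glycan tree type.  11 sialylated (-1 each) + 2 sulfated (-1 each) = -13 e.
glycans:
  - {site: 1,  tree: SIALYL_T}
  - {site: 2,  tree: SIALYL_T}
  - {site: 3,  tree: TN}
  - {site: 5,  tree: SIALYL_T}
  - {site: 7,  tree: SIALYL_T}
  - {site: 8,  tree: SIALYL_T}
  - {site: 9,  tree: SULFO_T}
  - {site: 11, tree: TN}
  - {site: 12, tree: SIALYL_T}
  - {site: 13, tree: SIALYL_T}
  - {site: 15, tree: SIALYL_T}
  - {site: 16, tree: TN}
  - {site: 17, tree: SIALYL_T}
  - {site: 19, tree: SIALYL_T}
  - {site: 21, tree: TN}
  - {site: 22, tree: SIALYL_T}
  - {site: 23, tree: TN}
  - {site: 25, tree: SULFO_T}
# Glycan trees: nodes are sugar residues, edges are glycosidic linkages
# (donor provides the anomeric carbon, acceptor provides the bridging
# oxygen).  The root sugar is the glycosyl donor to the Thr/Ser side chain.
trees:
  TN:        # GalNAc-alpha-O-Ser/Thr (Tn antigen), neutral
    sugars:
      - {id: 1, resname: GALNAC}
    linkages: []
    root: 1
  SIALYL_T:  # Neu5Ac-a2,3-Gal-b1,3-GalNAc (sialyl-T), charge -1
    sugars:
      - {id: 1, resname: GALNAC}
      - {id: 2, resname: GAL}
      - {id: 3, resname: NEU5AC}
    linkages:
      - {donor: 2, acceptor: 1, label: "b1-3"}
      - {donor: 3, acceptor: 2, label: "a2-3"}
    root: 1
  SULFO_T:   # Gal-6S-b1,3-GalNAc, charge -1
    sugars:
      - {id: 1, resname: GALNAC}
      - {id: 2, resname: GALS}
    linkages:
      - {donor: 2, acceptor: 1, label: "b1-3"}
    root: 1
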