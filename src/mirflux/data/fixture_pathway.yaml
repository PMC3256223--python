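# Desk-scale EGFR signaling pathway fixture.
#
# Central cascade: EGFR + EGF -> PI3K -> PIP3 -> PDPK1 -> AKT -> substrate
# proteins, with a parallel MEK/ERK branch.  Gene families that act as one
# functional unit (MEK, ERK, AKT, PKC, CAMK, CDKN1) are set entities
# simulated as a single place.  All protein-coding genes are expressed at a
# basal level of 1 nM; miRNA genes are silent until an experiment dials
# them up.  EGF, ATP, ADP and the PIP2 lipid pool are clamped at 1 nM.
genes:
  - EGFR
  - {id: MDM2}
  - {id: PIK3CA}
  - {id: PIK3R1}
  - {id: TP53}
  - {id: PTEN}
  - {id: CDKN1, members: [CDKN1A, CDKN1B]}
  - {id: AKT, members: [AKT1, AKT2, AKT3]}
  - {id: MYC}
  - {id: MTOR}
  - {id: ERK, members: [MAPK1, MAPK3]}
  - {id: RPS6KA5}
  - {id: CAMK, members: [CAMK2A, CAMK2B]}
  - {id: PKC, members: [PRKCA, PRKCB]}
  - {id: PDPK1}
  - {id: ELK1}
  - {id: TARBP2}
  - {id: RNASEN}
  - {id: DICER1}
  - {id: DGCR8}
  - {id: MEK, members: [MAP2K1, MAP2K2]}
  - {id: BAD}
mirnas:
  - mir-192
  - mir-181c
  - mir-489
  - mir-34a
  - {id: mir-TRDD, members: [mir-631, mir-608, mir-604, mir-492, mir-30a]}
species:
  - {id: EGF, role: protein, compartment: extracellular, clamp: 1.0}
  - {id: ATP, role: compound, compartment: cytoplasm, clamp: 1.0}
  - {id: ADP, role: compound, compartment: cytoplasm, clamp: 1.0}
  - {id: PIP2, role: compound, compartment: plasma_membrane, clamp: 1.0}
reactions:
  # receptor layer
  - {rtype: complex_formation, substrates: [EGFR-1, EGF], products: ["EGFR-1:EGF"]}
  # PI3K assembly and activation by the ligand-bound receptor
  - {rtype: complex_formation, substrates: [PIK3CA-1, PIK3R1-1], products: [PI3K]}
  - {rtype: activation, substrates: [PI3K], products: [Active-PI3K], enzyme: "EGFR-1:EGF"}
  # phosphatidylinositol signaling; PTEN antagonizes PIP3
  - {rtype: phosphorylation, substrates: [PIP2, ATP], products: [PIP3, ADP], enzyme: Active-PI3K}
  - {rtype: dephosphorylation, substrates: [PIP3], products: [PIP2], enzyme: PTEN-1}
  # AKT branch
  - {rtype: activation, substrates: [PDPK1-1], products: [Active-PDPK1], enzyme: PIP3}
  - {rtype: phosphorylation, substrates: [AKT-1, ATP], products: [P-AKT, ADP], enzyme: Active-PDPK1}
  - {rtype: dephosphorylation, substrates: [P-AKT], products: [AKT-1]}
  - {rtype: phosphorylation, substrates: [BAD-1, ATP], products: [P-BAD-1, ADP], enzyme: P-AKT}
  - {rtype: dephosphorylation, substrates: [P-BAD-1], products: [BAD-1]}
  - {rtype: phosphorylation, substrates: [TP53-1, ATP], products: [P-TP53, ADP], enzyme: P-AKT}
  - {rtype: phosphorylation, substrates: [MDM2-1, ATP], products: [P-MDM2, ADP], enzyme: P-AKT}
  - {rtype: phosphorylation, substrates: [CDKN1-1, ATP], products: [P-CDKN1, ADP], enzyme: P-AKT}
  - {rtype: phosphorylation, substrates: [MTOR-1, ATP], products: [P-MTOR, ADP], enzyme: P-AKT}
  # MEK/ERK branch
  - {rtype: phosphorylation, substrates: [MEK-1, ATP], products: [P-MEK, ADP], enzyme: "EGFR-1:EGF"}
  - {rtype: phosphorylation, substrates: [ERK-1, ATP], products: [P-ERK, ADP], enzyme: P-MEK}
  - {rtype: dephosphorylation, substrates: [P-ERK], products: [ERK-1]}
  - {rtype: phosphorylation, substrates: [ELK1-1, ATP], products: [P-ELK1, ADP], enzyme: P-ERK}
  - {rtype: phosphorylation, substrates: [MYC-1, ATP], products: [P-MYC, ADP], enzyme: P-ERK}
  - {rtype: phosphorylation, substrates: [RPS6KA5-1, ATP], products: [P-RPS6KA5, ADP], enzyme: P-ERK}
  # Ca2+/PKC side branch
  - {rtype: activation, substrates: [PKC-1], products: [Active-PKC], enzyme: PIP3}
  - {rtype: activation, substrates: [CAMK-1], products: [Active-CAMK], enzyme: Active-PKC}
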