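# ATM Pathway (DNA repair) — curated demonstration pathway.
#
# Gene roles (arr) are an editorial reconstruction from the textbook DNA
# damage-response wiring: the MRN sensor complex (MRE11/RAD50/NBN) recruits
# and activates ATM at double-strand breaks; active ATM phosphorylates CHK2,
# p53, SMC1 and histone H2AX, engaging checkpoints and repair.  MDM2 and the
# phosphatase WIP1 (PPM1D) antagonize the response; CDC25A is degraded upon
# checkpoint activation.  Users analysing their own data should supply their
# pathway database in this same format.
pathway_id: atm_dna_repair
nodes:
  - {gene: ATM, arr: 1.0}
  - {gene: CHEK2, arr: 1.0}
  - {gene: TP53, arr: 1.0}
  - {gene: SMC1A, arr: 1.0}
  - {gene: H2AFX, arr: 1.0}
  - {gene: MDC1, arr: 1.0}
  - {gene: MRE11, arr: 0.5}
  - {gene: RAD50, arr: 0.5}
  - {gene: NBN, arr: 0.5}
  - {gene: BRCA1, arr: 0.5}
  - {gene: CDC25A, arr: -0.5}
  - {gene: MDM2, arr: -1.0}
  - {gene: PPM1D, arr: -1.0}
edges:
  - {from: MRE11, to: ATM, kind: activation}
  - {from: RAD50, to: ATM, kind: activation}
  - {from: NBN, to: ATM, kind: activation}
  - {from: ATM, to: CHEK2, kind: activation}
  - {from: ATM, to: TP53, kind: activation}
  - {from: ATM, to: SMC1A, kind: activation}
  - {from: ATM, to: H2AFX, kind: activation}
  - {from: ATM, to: BRCA1, kind: activation}
  - {from: H2AFX, to: MDC1, kind: activation}
  - {from: CHEK2, to: CDC25A, kind: inhibition}
  - {from: MDM2, to: TP53, kind: inhibition}
  - {from: PPM1D, to: ATM, kind: inhibition}
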