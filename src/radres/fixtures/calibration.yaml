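# Study-shaped calibration for the synthetic-data generator.
#
# The drug panel, culture concentrations, plate concentration series and the
# IC50 time-course table are taken from the study design this package
# emulates; the IC50 entries are the printed measured values (strings encode
# censored ">=50", "NS" = not significant, "ND" = not detected).  Foci means
# are per-condition scenario values: only the naive NGP-127 spontaneous pATM
# rate (6.6 foci/nucleus) is a study-reported calibration point; the other
# means are chosen to reproduce the reported qualitative contrasts (TKI-grown
# SKOV-3 repairs 35-50% of residual gammaH2AX foci, SKOV-3 has far fewer pATM
# foci than NGP-127, etc.) at realistic scale.

cell_lines: [SKOV-3, NGP-127]
drugs: [Sorafenib, Pazopanib, Sunitinib, Everolimus, Temsirolimus]
drug_classes:
  TKI: [Sorafenib, Pazopanib, Sunitinib]
  rapalog: [Everolimus, Temsirolimus]
weeks: [4, 8, 12, 16, 20]

culture_concentrations_uM:
  Sorafenib: 10
  Pazopanib: 25
  Sunitinib: 6
  Everolimus: 20
  Temsirolimus: 15

plate_concentrations_uM: [0, 0.8, 1.56, 3.1, 6.25, 12.5, 25, 50]

# Measured IC50 (uM) by cell line / drug / culturing week (week 0 = naive
# control).  Used both as the truth profile for simulated plates and as the
# printed-table input for resistance arithmetic.
ic50_table_uM:
  NGP-127:
    Sunitinib: {0: 3.1, 4: 2.4, 8: 3.3, 12: 4.9, 16: 10.8, 20: 8.4}
    Sorafenib: {0: 5.5, 4: 6.2, 8: 6.8, 12: 8.1, 16: 7.9, 20: 9.0}
    Pazopanib: {0: 12.0, 4: 13.9, 8: ND, 12: 14.7, 16: 22.4, 20: 24.4}
    Temsirolimus: {0: 11.8, 4: 12.3, 8: 14.7, 12: 15.4, 16: 27.9, 20: 33.7}
    Everolimus: {0: 15.5, 4: 16.4, 8: 18.2, 12: 19.6, 16: 43.0, 20: 37.9}
  SKOV-3:
    Sunitinib: {0: 3.0, 4: 3.0, 8: 3.6, 12: ND, 16: 4.1, 20: 6.0}
    Sorafenib: {0: 9.6, 4: 10.2, 8: 10.7, 12: ND, 16: 13.2, 20: 12.0}
    Pazopanib: {0: '>=50', 4: NS, 8: NS, 12: NS, 16: NS, 20: NS}
    Temsirolimus: {0: 17.0, 4: 15.8, 8: 17.5, 12: ND, 16: 15.4, 20: 24.9}
    Everolimus: {0: 17.6, 4: 19.5, 8: 18.6, 12: ND, 16: 18.6, 20: 30.9}

# Expression time-course effects: pathway-member genes shift by
# sign(arr) * magnitude * exp(-decay * week) log10 units, with a per-drug
# lognormal jitter of the magnitude (sd in log space) so dispersion across
# drugs decays with week.  Only SKOV-3 x TKI activates the DNA-repair
# pathway in the default scenario; the contrast is switchable, not wired in.
pathway_effects:
  - cell_line: SKOV-3
    drug_class: TKI
    pathway: atm_dna_repair
    magnitude: 0.4
    decay: 0.08
    drug_jitter_sd: 0.3

# Mean foci per nucleus [gammaH2AX, pATM] per condition; "spont" =
# non-irradiated, "irr" = 24 h after 10 Gy.  Washout conditions (drug removed
# 48 h before irradiation) reuse these means: in the emulated scenario the
# adaptation persists after drug removal.
foci_means:
  SKOV-3:
    naive:        {spont: [2.5, 1.5], irr: [10.0, 4.0]}
    Sorafenib:    {spont: [2.5, 1.5], irr: [6.5, 2.9]}
    Pazopanib:    {spont: [2.5, 1.5], irr: [6.0, 3.0]}
    Sunitinib:    {spont: [2.5, 1.5], irr: [5.5, 3.1]}
    Everolimus:   {spont: [2.5, 1.5], irr: [9.8, 3.9]}
    Temsirolimus: {spont: [2.6, 1.5], irr: [10.1, 4.0]}
  NGP-127:
    naive:        {spont: [3.0, 6.6], irr: [12.0, 13.0]}
    Sorafenib:    {spont: [2.0, 5.0], irr: [14.4, 12.6]}
    Pazopanib:    {spont: [2.2, 5.3], irr: [14.4, 13.0]}
    Sunitinib:    {spont: [3.0, 8.6], irr: [12.0, 14.6]}
    Everolimus:   {spont: [3.1, 8.0], irr: [12.6, 14.0]}
    Temsirolimus: {spont: [3.1, 7.9], irr: [12.5, 14.0]}

# Noise model defaults
noise:
  probe_cv: 0.10          # multiplicative probe replicate noise
  od_cv: 0.05             # OD noise, fraction of control OD
  experiment_cv: 0.05     # lognormal between-experiment foci multiplier
hill_default: 1.2
viability_floor: 2.0
viability_ceiling: 100.0
censored_true_ic50_uM: 120.0   # truth behind ">=50" censored entries
n_cells_per_experiment: 200
n_experiments: 3
n_control_reps: 5
n_genes: 3706
n_probes: 6020
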