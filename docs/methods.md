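# Methods

This note documents the models, parameter choices and numerical conventions
behind `radres`, and what the synthetic-data tests do and do not establish
about real data.

## Expression processing

Probe-level signals are strictly positive fluorescence/electrochemical
intensities in arbitrary units.  Signals ≤ 0 are floored to 1e−6 before any
logarithmic operation (an undetectable signal, not a biological zero); each
flooring event is logged, and flooring can be disabled, in which case
non-positive signals are rejected.  All probes of a gene are collapsed per
sample by the geometric mean — the natural average for multiplicative
intensity noise — and genes are ordered lexicographically.

Quantile normalization forces every sample column onto the common mean
distribution: the value at rank r becomes the mean across columns of each
column's rank-r value.  Ties receive the average of the replacement values
over the tied ranks.  This tie rule is one of two dialects in circulation
(the other interpolates the mean quantile function at the average rank, as
limma's `normalizeQuantiles(ties=TRUE)` does); both agree exactly on
tie-free data, which is why the exact "identical column multiset" and
idempotence properties are asserted on continuous data only, with a
dedicated hand-computed test for ties.  Normalization is run within each
cell line's sample block by default — chips of one line form one batch —
and can be pooled across lines via `per_cell_line=False`.

The matrix file dialect is TSV with 6 significant digits; round-tripping is
exact at that precision.

## Pathway activation scoring

For a case sample against a control group, CNR_n = x_n(case) /
geomean(x_n(controls)).  A gene is flagged differentially expressed when
its case value falls outside mean ± 2 sd of the controls (sample sd, n−1;
at least 2 controls required, the emulated design uses 5).  The pathway
score is PAS_p = Σ_n ARR_np · BTIF_n · lg(CNR_n), with ARR ∈ {±1, ±0.5, 0}
and BTIF the boolean flag.  The flag is boolean rather than a continuous
importance weight: the two-sigma rule is the only differential-expression
rule defined for this chain, and gating (rather than weighting) makes the
null behavior transparent (PAS ≡ 0 when nothing is flagged).

Pathway genes absent from the chip contribute zero and are logged, so an
arbitrary chip design can be scored; a pathway with no overlap scores 0
with a warning.  Edges (activation/inhibition) are carried for rendering
only — the score is node-role based, not topology-propagating.  In the
exported GraphML/DOT, node color depth is lg CNR clamped to [−1, +1]
(missing CNR renders neutral 0), activation edges are green, inhibition
red, and the graph carries its PAS as an attribute.

Time-course scoring matches each drug sample to the naive controls of the
same cell line and week (pooling across weeks is available but not the
default, because adaptation-phase drift would otherwise contaminate the
control distribution).  Per-week dispersion is the population (ddof 0)
standard deviation of PAS across the drug samples of that week, so a
single-drug week reports 0 rather than NaN.

The shipped "ATM pathway (DNA repair)" fixture is a 13-gene editorial
reconstruction of the canonical double-strand-break response (MRN sensor →
ATM → CHK2/p53/SMC1/H2AX effectors, with MDM2/WIP1 antagonists); its role
assignments are documented in the file header and it is a demonstration
and test object, not a substitute for a full pathway database.

## Dose–response analysis

Viability = (OD_treated − OD_blank)/(OD_control − OD_blank) × 100%, not
clipped (values > 100% indicate growth stimulation).  The 4-parameter
logistic is fitted by least squares on log10 concentration over all
replicate wells; the zero-dose wells only define 100% viability and are
excluded from the log-scale fit (the standard dose–response convention).
Initialisation: ceiling = max mean viability, floor = min, IC50 = the
concentration nearest the 50% crossing, hill = 1.  Bounds: IC50 ∈
[min dose/10, max dose·10], hill ∈ [0.2, 8], floor ∈ [0, 60]%, ceiling ∈
[60, 150]%.  The floor/ceiling bounds encode that viability is normalized
to the untreated controls; leaving them unbounded lets shallow-hill fits
trade the floor against the midpoint and roughly doubles the IC50 error on
noisy plates.

Censoring: plates with ≥ 90% mean viability everywhere, fits whose IC50
exceeds the top tested dose, and curves that never reach their midpoint
within the range all report "≥ max dose"; all-dead plates (≤ 10%
everywhere) report "≤ min dose".  Censoring is distinct from the
missing-data marker ("Not detected") used when a measurement does not
exist.  Non-monotone plates are not rejected: fits with RMSE > 15 viability
points are flagged low-confidence.

Percent change of IC50 versus baseline is rounded half-up to an integer.
On the emulated study's printed 20-week IC50 pairs this reproduces the
printed percentages for all but two cells (computed 171% vs printed 174%,
103% vs 104%), which are attributable to the authors rounding IC50 before
printing; the test suite documents them as known-off cells with a ≤ 3-point
bound instead of forcing agreement.

## Foci statistics

Summaries are hierarchical: per-experiment cell means first, then grand
mean and SE = sd(experiment means)/√n over the n = 3 independent
experiments.  Cells within an experiment share staining, irradiation and
imaging conditions, so pooling all cells would understate the SE whenever
between-experiment variance exists (a property test asserts hierarchical
SE ≥ pooled SE in that regime).  For the same reason the Student t-test
(two-sided, equal variance) runs on experiment-level means, n = 3 per
group, df = 4 — not on pooled cells, which would inflate significance.
A single-experiment condition reports SE as missing with a warning.

Radiation-induced focus excess is mean(irradiated) − mean(mock), SE
propagated in quadrature; negative values are allowed but flagged.  Percent
reduction versus naive cells is reported two ways: on total residual foci
(the headline, since residual unrepaired breaks are the radioresistance
criterion) and on background-subtracted induced foci.

## Synthetic-data generator

The generator is a pure function of (config, seed); independent seeded
streams drive expression, plates and foci, so each can be regenerated
alone.  Defaults come from the packaged calibration and mirror the emulated
design: 2 cell lines × 5 drugs × weeks {4,8,12,16,20}, 5 naive replicates
per week, 6020 probes / 3706 genes (genes carry 1–2 probes so the probe
total is exact), 8-point 0.8–50 μM quadruplicate plates, 200 cells × 3
experiments per foci condition.

* **Expression** — per-gene baseline lg expression ~ N(2.0, 0.5); drug
  samples shift pathway-member genes by sign(ARR) · magnitude ·
  exp(−decay · week) lg units with a per-(drug, week) lognormal jitter
  (sd 0.3) of the magnitude, so the across-drug PAS dispersion decays with
  week; probe replicate noise is lognormal with 10% CV.  The default
  scenario activates the DNA-repair pathway (magnitude 0.4, decay
  0.08/week) for TKIs in SKOV-3 only; it is a switchable calibration entry,
  not hard-coded truth, and `effect_scale=0` yields null data.
* **Plates** — OD = blank + span · v/100 + N(0, 0.05 · span) with the 4PL
  at the calibrated "true" IC50 (the measured time-course table; censored
  "≥50" entries use a 120 μM truth so the plate stays high through 50 μM,
  and "ND"/"NS" entries produce no plate), hill 1.2, floor 2%, ceiling
  100%.
* **Foci** — per-cell Poisson counts around the condition mean times a
  lognormal between-experiment multiplier (5% CV, shared by both markers
  within an experiment).  The Poisson-with-multiplier form is the minimal
  hierarchical model for counts with experiment-level batch effects.  Of
  the calibrated means, only the naive NGP-127 spontaneous pATM rate
  (6.6 foci/nucleus) is a study-reported value; the others are scenario
  choices reproducing the reported qualitative contrasts.  Washout
  conditions reuse the corresponding means (the emulated scenario keeps
  the adaptation after drug removal).

Noise defaults (probe CV 10%, OD noise 5% of control span, experiment CV
5%) were chosen once so that study-scale effects are detectable at
study-scale sample sizes; all are overridable.

What passing tests on generated data show — and do not show: they verify
the pipeline's arithmetic, calibration and statistical behavior under a
known truth.  They do not validate the biological findings of any real
experiment; real chips have probe-specific affinities, spatial artefacts
and batch structure that the lognormal noise model does not emulate, real
dose–response curves need not be 4PL, and real focus counts are typically
overdispersed beyond Poisson.

## Problem sizes and numerical conventions

The unit-test suite runs the full design at a 40-gene chip scale; the
acceptance checks use 200 plates for IC50 recovery, 500 simulation runs for
detection power, 5 seeds at full foci scale for calibration recovery, and a
reduced two-week two-drug design for byte-identity checks — sizes chosen to
make the statistical assertions stable while keeping the suite fast.
TSV floats are written with 6 significant digits; determinism is asserted
at the byte level on written files.  PAS per-gene terms sum exactly to the
reported PAS (checked to 1e−9); brute-force oracles in the test suite
recompute PAS independently of the implementation.

## Known limitations

* PAS here is node-role scoring; topology-aware propagation is out of
  scope, edges exist for rendering.
* The shipped pathway fixture is a reconstruction; role values (ARR) for
  the real database are proprietary and must be supplied by the user.
* IC50 censoring reports a bound, not an interval estimate; no confidence
  intervals are attached to fitted parameters.
* The t-test assumes equal variances on n = 3 experiment means, matching
  the emulated design; it is not robust to strong variance heterogeneity.
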