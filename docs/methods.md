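# Methods

## Matched-pair qPCR array analysis

Each sample's Ct vector is normalized to the mean Ct of the miRNAs *detected
in that sample* (global-mean normalization): ΔCt_i = Ct_i − mean(Ct over
detected). Reactions with missing Ct or Ct ≥ the detection limit (default 40
cycles) are undetected. For a matched pair, ΔΔCt = ΔCt_post − ΔCt_pre and the
expression ratio is 2^(−ΔΔCt). Ratios are displayed on the signed-fold
convention (r < 1 → −1/r), so |fold| ≥ 1 always and down-regulation carries a
minus sign.

Undetected handling, in order:

* the normalization mean uses detected miRNAs only — an imputed value is a
  bound, not a measurement, and must not pull the sample reference;
* if exactly one side of a pair is undetected, its Ct is imputed at the
  detection limit *after* the means are computed; the resulting fold is a
  bound, flagged `is_estimate`;
* if both sides are undetected the record is missing — it carries no
  directional evidence and disqualifies that miRNA from the consistency
  filter.

Estimated bounds participate in the consistency filter (same sign, |fold| > 1
in every case) and the magnitude filter (|fold| ≥ `min_fold`, default 1.3, in
every case) at their bound value, but are excluded from mean fold
differences. The mean is the arithmetic mean of the post/pre *ratios* over
non-estimate cases, converted back to a signed fold. This ratio-scale signed
averaging is the unique convention that reproduces both the up-regulated and
the down-regulated summary rows of the built-in reference fold table
(`mirchemo.datasets`); two rows of that table (miR-625, miR-885-5p) disagree
with their printed means in the third digit, consistent with the original
means having been computed from unrounded per-case values, and are documented
rather than forced.

A single-reference normalizer (`normalize_to_reference`) supports follow-up
qPCR where one endogenous control (RNU48 for miRNA, ACTB for mRNA) replaces
the array-stage global mean.

Note one intrinsic property of global-mean normalization: planted or real
expression changes shift the post-sample mean, so recovered folds are
attenuated by 2^(mean of the planted log2 ratios)/panel size. With a handful
of changed miRNAs on a 377-miRNA panel the attenuation is ≈1%, and it is
exactly zero when up- and down-shifts balance (the zero-noise generator test
uses such a balanced plant).

## Pulldown enrichment

Counts are normalized to reads per million after adding a pseudocount of 0.5
to every gene (totals recomputed after the addition), keeping enrichment
ratios defined when the scrambled-control pulldown has zero reads; such
pseudocount-dominated ratios are flagged. A gene is a candidate target when
RPM(mimic pulldown) / RPM(control pulldown) ≥ the threshold (default 100).
Input (lysate) samples are normalized and reported but do not gate
candidacy. Because RPM renormalizes to the realized library, strong planted
enrichment deflates every other gene's RPM in the mimic pulldown by the
planted-mass inflation factor; with planted targets modelled as moderately
expressed (0.35× the mean null abundance, 20 genes at 200-fold, 10^6 reads)
the observed ratio of true targets is ≈140–200, comfortably above threshold,
while null ratios concentrate near the inverse inflation factor (≈0.7).

## Target consensus

Predictions from the five algorithms are combined by support count: a gene
is in the consensus at level k if at least k algorithms predict it (default
k = 5; k = 4 is the standard relaxation). Final nominees are the
intersection of the consensus with the pulldown candidates. Gene symbols are
upper-cased and whitespace-stripped before matching; pulldown symbols absent
from the prediction table are reported in `unmatched_`, never silently
dropped.

## Chemoresponse assays

Technical replicates are averaged within each biological replicate first;
biological replicates are the unit of analysis throughout. Survival is
normalized twice: each biological replicate's signal is divided by its own
vehicle (dose 0) mean, and the targeted condition's relative survival is then
divided by the matched control transfection's, per biological replicate and
dose — all relative quantities are therefore invariant to linear rescaling of
raw absorbance within a biological replicate. Differences are tested with
paired one-tailed t tests over biological replicates (direction fixed by
hypothesis: mimics and siRNA increase survival, inhibitors decrease it); a
zero-variance difference vector is degenerate and reported as p ∈ {0, 0.5, 1}
by sign with a flag. Per-dose SD and SEM are both reported.

Clonogenic assays: plating efficiency = colonies / cells seeded (a colony
being >30 cells, decided at counting time upstream); surviving fraction =
PE(treated)/PE(vehicle).

ICxx is defined on the relative-survival scale as the dose where survival
equals 1 − xx/100, obtained by linear interpolation of survival against
log10(dose) between the bracketing observed doses (first down-crossing; exact
grid hits returned as-is; no extrapolation, no parametric fit — on a
six-dose grid spanning the IC50 the interpolation bias against a Hill-slope-1
logistic is under 1%). Fold resistance is the ratio of ICxx values.

## Survival analysis

Expression is dichotomized on cohort z-scores: low ⟺ z strictly below the
cutoff (−0.82 SD for disease-free survival, −0.75 SD for disease-specific
survival; a z exactly at the cutoff is high). Kaplan–Meier curves use the
product-limit estimator with right censoring, events preceding censorings at
tied times; group comparison uses the unweighted log-rank test (1 df).
z-scores are taken as supplied (cohort-level); `rescale_within_subgroup=True`
re-standardizes within each subgroup instead. Subgroup analyses
(chemotherapy yes/no, ER±, HER2±) rerun the dichotomized test independently
per subgroup; records with unknown annotation are excluded from that split
and counted. Product-limit estimation and the log-rank statistic are
computed via lifelines; the test suite checks both against hand-tabulated
small-instance computations.

## Synthetic data

The generators produce every input table with planted ground truth under one
`SimulationConfig`; a single integer seed feeds a `numpy.random.SeedSequence`
whose spawned children give each generator an independent stream, so outputs
are byte-reproducible jointly and individually.

Defaults mirror the scale of the motivating study design: 377-miRNA arrays
over 5 matched pairs; Ct noise SD 0.15 cycles and dropout at 40 cycles;
planted fold changes of 2–4.9 in both directions (the magnitudes of the two
focal miRNAs' observed mean changes); ~6000-gene count tables at 10^6 reads
with 20 targets planted at 200-fold; a 2000-patient cohort with 21% treated
with chemotherapy, hazard ratio 2 for low expressors in the chemotherapy arm
only, exponential event and censoring times at a 30% censoring rate; logistic
(Hill slope 1) viability curves over 30 nM–1 µM epirubicin-like doses with
5% multiplicative signal noise and 3×3 replicates; binomial clonogenic
counts at plating efficiency 0.6.

What the generators do not emulate: FFPE RNA degradation, array chemistry
and batch effects beyond Gaussian Ct noise; over-dispersed (beyond-Poisson)
sequencing counts; correlated prediction-algorithm errors; non-proportional
hazards, competing risks or covariate-dependent censoring; assay edge
effects. Passing recovery tests on these simulations therefore demonstrates
the correctness and calibration of the *analysis*, not robustness to every
artefact of real data.

Two quantitative notes on recovery under the defaults. First, the per-case
magnitude filter is intentionally strict: at Ct noise SD 0.15 a true
1.5-fold change passes the 1.3-fold rule in any one case with probability
≈0.84, so five-case sensitivity at that boundary is ≈0.4 by construction;
the planted defaults (≥2-fold) reflect the effect sizes the filter is meant
to retain, and there sensitivity exceeds 0.99 with specificity ≈1. Second,
IC50 ratios estimated from single simulated plates scatter by ≈10%
(replicate noise through the vehicle normalization), so ratio-recovery
checks average a handful of simulated plates.

## Pipeline and IO

All tables are tab-separated UTF-8 with a header row and `NA` for missing
values. Readers validate against named schemas (required columns, numeric
types, unique keys) and fail with the offending file, column and row. The
orchestrator runs stages in study order (miRNA discovery → chemoresponse →
target nomination → survival), writes per-stage TSVs and a JSON manifest
(package version, seed, thresholds, SHA-256 of every input), and aborts with
the stage name on failure. The CLI (`mirchemo`) exposes `simulate`, `ddct`,
`pulldown`, `targets`, `chemo`, `survival` and `run-all`; validation errors
exit with code 2, computation failures with code 3.

## Known limitations

* The enrichment rule is the ratio threshold alone; no count-model testing
  (e.g. negative-binomial differential analysis) is layered on top, and
  expression in the input samples is not required for candidacy.
* ICxx interpolation requires the curve to bracket the target level; assays
  whose dose range misses it return an error rather than an extrapolation.
* The survival module implements dichotomized log-rank comparisons only — no
  Cox regression or multivariate adjustment.
* Prediction tables are static exports; the five algorithms are not re-run.
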