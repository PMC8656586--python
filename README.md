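# mirchemo

A tested, reusable pipeline for discovering chemoresistance-associated
microRNAs from matched pre/post-chemotherapy tumour samples and following
them through to a survival-predictive target gene.

Neoadjuvant chemotherapy (drug treatment before surgery) makes matched tumour
tissue available from before and after therapy. Comparing microRNA expression
in the cancer cells of those matched samples highlights expression changes in
the cells that survived treatment — candidate resistance drivers. This
package implements the downstream analysis of such a study end to end, for
bioinformaticians and wet-lab groups who have the measured tables (qPCR array
Ct values, pulldown RNA-seq counts, prediction exports, assay plates,
clinical cohorts) and need the statistics reproducibly:

1. **`mirchemo.qpcr`** — matched-pair qPCR array analysis. Per-sample
   global-mean normalization, ΔCt = Ct − mean(Ct over detected miRNAs);
   per-case fold = 2^(−ΔΔCt) with ΔΔCt = ΔCt_post − ΔCt_pre; singly
   undetected reactions imputed at the 40-cycle detection limit and flagged
   as estimated bounds; folds reported on the signed convention (ratio r < 1
   shown as −1/r). Filters: direction consistency in every case, then a
   per-case minimum magnitude (default 1.3-fold). Mean fold differences are
   arithmetic means on the ratio scale, excluding estimated bounds.
2. **`mirchemo.pulldown`** — candidate targets from biotin-tagged mimic
   pulldown RNA-seq: reads-per-million normalization (pseudocount 0.5) and a
   ≥100-fold mimic-vs-scrambled-control over-representation rule.
3. **`mirchemo.targets`** — k-of-5 consensus over miRanda, PicTar,
   TargetScan, RNA22 and PITA predictions, intersected with pulldown hits.
4. **`mirchemo.chemo`** — MTT and clonogenic dose–response: survival
   relative to vehicle, then relative to the control transfection; paired
   one-tailed t tests over biological replicates; ICxx by log-dose
   interpolation; clonogenic plating efficiency and surviving fraction.
5. **`mirchemo.survival`** — expression-dichotomized Kaplan–Meier curves
   (low = z-score strictly below a cutoff, default −0.82 SD) with unweighted
   log-rank tests, run on the full cohort and within treatment/receptor
   subgroups.
6. **`mirchemo.simulate`** — seeded generators for every input table with
   planted ground truth, so the whole pipeline is testable without any
   external data.

Each stage is an sklearn-style estimator (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`); module-level functions
expose the individual operations.

## Worked example

The built-in fold-change table (`mirchemo.datasets.load_nac_fold_table`)
holds per-case signed folds for the 12 miRNAs that changed consistently
across five matched ER-positive breast cancer pairs:

```python
from mirchemo import qpcr
from mirchemo.datasets import load_nac_fold_table

folds = load_nac_fold_table()
sub = folds[folds.mirna_id == "miR-195"]
print(round(qpcr.mean_signed_fold(sub.signed_fold, sub.is_estimate), 2))
print(sorted(qpcr.magnitude_filter(folds, min_fold=1.3)))
```

prints

```
2.57
['miR-195', 'miR-26b']
```

— miR-195 rose by a mean 2.57-fold after therapy, and only miR-195 and
miR-26b exceed 1.3-fold in every single case (the other 10 consistent miRNAs
are excluded by the per-case magnitude rule).

A full synthetic run from the shell:

```bash
mirchemo run-all --simulate-first --seed 7 --outdir out/
```

simulates all inputs (377-miRNA Ct arrays over 5 pairs, pulldown counts,
prediction tables, viability plates, a 2000-patient cohort) and writes every
stage's output TSVs plus a run manifest; the planted miRNAs, the planted
SEMA6D target and the chemotherapy-arm-only survival effect are all
recovered.

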