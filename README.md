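# mutsense

Predict **active-site**, **buried**, and **exposed non-active-site** residues
from deep mutational scanning (DMS) data combined with sequence-predicted
solvent accessibility — no 3-D structure required at prediction time.

## Method

1. **Rescale** raw per-mutation effect scores to [-1, 0]: the 5th percentile
   of all scores maps to -1 and the wild-type peak of the score histogram
   (median of the modal bin) maps to 0.
2. **Average** rescaled scores per position, keeping positions with at least
   10 observed mutants. Per-position *sensitivity* is the negated mean
   (1 = fully mutation-sensitive).
3. **Combine** standardized sensitivity with standardized predicted relative
   accessibility: `score_active = z_sens + z_acc` (sensitive *and* exposed),
   `score_buried = z_sens - z_acc` (sensitive *and* inaccessible).
4. **Call** a residue for a class when its combined score exceeds the mean by
   one population SD; everything else is exposed non-active-site. Residues
   exceeding both cutoffs are tie-broken by the larger SD-normalized margin
   and flagged `ambiguous_dual_call`.
5. **Evaluate** one-vs-rest per class: sensitivity, specificity, accuracy and
   MCC, plus unweighted cross-dataset means.

A seeded synthetic generator (`mutsense.synthetic`) produces DMS score
tables, true/noisy-predicted accessibility and truth labels with realistic
class structure (buried positions tolerate aliphatic substitutions unless
the wild type is Ala/Gly; active-site positions are uniformly sensitive), so
the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset
mutsense simulate --config cfg.yaml --seed 7 --out sim/

# predict residue classes
mutsense predict --scores sim/scores.tsv --pred-acc sim/pred_acc.tsv --out run/

# score against truth labels
mutsense evaluate --pred run/predictions.tsv --truth sim/truth.tsv --dataset-id demo --out eval/

# aggregate several datasets into a summary table
mutsense report --metrics eval/metrics.tsv --metrics eval2/metrics.tsv --out summary.tsv
```

`predict` accepts a YAML config with keys `percentile`, `n_bins`,
`min_mutants`, `k_sd`, `clamp`, `exclusions` (positions removed from the
buried call, e.g. metal-coordinating cysteines), `numbering_offset`,
`min_M`/`max_M` (manual rescaling anchors) and `dialect`
(`long` = `position wt_aa mut_aa score`; `matrix` = position × 20 amino-acid
columns). Accessibility arrives either as a generic
`position rel_acc [method]` table or as a NACCESS `.rsa` file
(`mutsense.dms_io.read_rsa`, side-chain relative column). Every run writes a
`manifest.json` sufficient to reproduce its outputs.

## Layout

| module | role |
| --- | --- |
| `mutsense.dms_io` | table readers/writers, validation, residue indexing |
| `mutsense.rescale_aggregate` | score rescaling and per-position averaging |
| `mutsense.classify` | Z-score combination and three-class calling |
| `mutsense.evaluate` | confusion metrics, Pearson r, cross-dataset summaries |
| `mutsense.synthetic` | seeded synthetic DMS/accessibility/truth generator |
| `mutsense.pipeline_cli` | orchestration, config, CLI, run manifests |
| `mutsense.benchmarks` | checked-in published per-dataset reference tables |
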