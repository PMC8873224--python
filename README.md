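# fundusdr

Feature-based diabetic-retinopathy (DR) grading and progression analysis on
structured lesion annotations. Instead of end-to-end image classification,
the pipeline works from a per-image lesion set (type, centroid, area,
confidence) plus anatomical landmarks (optic-disc centre and diameter, fovea
centre), and maps it to a severity grade through configurable decision
tables — so the same lesion detections can be graded under either of two
interchangeable schemes without retraining anything.

## What's inside

- **`fundusdr.fundus_model`** — domain types and the disc/fovea-anchored
  geometry: distances in disc-diameter (DD) units, the five-region
  concentric partition around the fovea, and fovea-centred quadrants.
- **`fundusdr.grading`** — lesion-set summarisation (confidence filtering,
  per-region/per-quadrant counts), JSON decision tables for the two shipped
  schemes (five-level international scale with the 4-2-1 severe rule; UK
  screening R0–R3 with an M1 maculopathy flag), an exudate-proximity
  maculopathy surrogate, a referability policy, and a seeded random-forest
  alternative grader over 98-dimensional summary feature vectors.
- **`fundusdr.alignment_progression`** — closed-form similarity registration
  from the two landmarks, per-type greedy lesion matching, and a
  NEW / RESOLVED / GROWN / SHRUNK / STABLE change log aggregated per region.
- **`fundusdr.evaluation`** — lesion-conditioned TP/TN/FP/FN outcome
  definitions (overshooting the ground-truth severity is a false positive;
  non-referable findings on a non-referable image are a true negative),
  sensitivity/specificity/PPV/NPV with Wilson or Clopper–Pearson 95% CIs,
  quadratic weighted kappa, ROC/AUC with high-sensitivity and
  high-specificity operating points, prevalence subsampling, and the
  human-workload-reduction figure.
- **`fundusdr.synthetic_data`** — inverse-table synthesis of lesion sets for
  any target grade, cohort sampling with three prevalence presets
  (`kenya` 28 680 images, `saudi` 10 026, `china` 15 000), a detector noise
  model, longitudinal pairs with exact planted-change ground truth, and a
  simple raster phantom renderer + blob detector.
- **`fundusdr.io_cli`** — annotation JSON schema, ground-truth/grade/report
  CSVs, mask-PNG conversion, and the `fundusdr` command-line tool.

## CLI

```sh
# sample a 500-image synthetic cohort with detector noise
fundusdr simulate --preset china -n 500 --seed 1 --miss-prob 0.1 \
    --false-alarm-rate 0.2 --out runs/sim

# grade it under both schemes
fundusdr grade --annotations runs/sim/annotations.json --scheme nsc \
    --out runs/graded

# score against ground truth on the four binary screening tasks
fundusdr evaluate --grades runs/graded/grades.csv --gt runs/sim/gt.csv \
    --scheme nsc --ci wilson --out runs/eval

# lesion-level change log between two visits of one eye
fundusdr progress --baseline baseline.json --followup followup.json \
    --out runs/prog

# ROC + operating points from a scored table (image_id,score columns)
fundusdr roc --scores scores.csv --gt runs/sim/gt.csv --scheme nsc \
    --task REFERABLE --out runs/roc
```

Every command logs a JSON line (config hash, seed, counts) to stderr and
exits non-zero with a diagnostic on malformed input. Identical
configuration and seed produce byte-identical outputs.

## Decision tables

The grading rules live in JSON (`src/fundusdr/grading/tables/`): an ordered
list of rules, highest severity first, each with a disjunction of
conditions over the lesion summary (`present`, `min_count`,
`min_per_quadrant` + `min_quadrants`, `min_quadrants_present`, `min_area`,
`max_dd`). Pass `--table my_table.json` to swap a scheme's rules without
code changes; `tables/referability.json` holds the referable-level policy.

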