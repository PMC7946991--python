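# pannetrisk

Whole-slide image analysis pipeline for predicting metastasis risk in
pancreatic neuroendocrine tumors (PanNET), for computational-pathology
researchers who want a fully testable, desk-scale implementation of a
multi-stage tile-classification → slide-feature → survival workflow.

Up to 15% of resected PanNET patients develop distant metastasis, and no
morphology-based prognostic marker is in clinical use. The pipeline
implemented here stratifies patients from H&E whole-slide images in five
stages:

1. **Tissue annotation** — slides are cut into non-overlapping 150 px
   tiles (background excluded by a saturation rule) and a 5-class tile
   classifier (cancer, stroma-rich cancer, stroma, normal parenchyma,
   fat) produces a whole-slide class-probability map; training tiles are
   expanded ×46 by a fixed catalogue of orientation/hue/blur/noise/
   contrast augmentations. Whole-slide agreement with ground-truth
   regions is scored by the Jaccard index of the cancer region.
2. **Metastasis association** — tiles confidently annotated (p ≥ 0.95)
   as cancer, or as cancer-adjacent stroma, are relabeled with their
   patient's metastasis status and a per-compartment classifier trained
   under patient-grouped 5-fold CV emits out-of-fold tile scores
   s ∈ [0, 1].
3. **Slide features** — after a neighbor artifact filter (≥ 8 matching
   8-neighbors for cancer tiles, ≥ 3 for stroma), each slide's score
   distribution is summarized into 150 named features (75 per
   compartment): moments, 12 probability-band counts/proportions,
   high/low-tail moments, extremes, and spatial "hotspot" histograms
   (tiles above threshold per 10×10 block, in width-2 count bins);
   missing values are imputed by chained equations (10 iterations).
4. **Risk models** — per left-out patient (LOOCV), features are filtered
   by Welch two-sample t (|t| > 1.2 is the replication default, with the
   statistic t = (x̄₁−x̄₀)/√(s₁²/n₁+s₀²/n₀) recomputed inside every
   training fold), and an 18-model classifier zoo is evaluated on
   cancer-only / stroma-only / combined subsets. Patients are high-risk
   if any slide is positive. A nested LOOCV variant selects the t
   threshold by inner 10-fold log-loss and predicts with a 500-tree
   random forest on a reduced binary/broad-tail feature schema.
5. **Survival** — Kaplan-Meier with the log-rank test, and Cox
   proportional hazards (Efron ties, Wald p-values) adjusting the risk
   group for age, sex and tumor size.

Because clinical slides cannot be redistributed, the package ships a
first-class synthetic-data generator (`pannetrisk.synthgen`): five
blob-noise tissue textures arranged into annotated mosaics, a cohort
matching the study marginals (89 patients / 104 slides / 20%
metastatic), a planted texture shift in cancer/stroma regions of
metastatic patients, and exponential metastasis-free survival with a
planted hazard ratio — so every downstream stage can be validated
end-to-end against known ground truth. See `docs/methods.md` for the
model details and what the synthetic material does and does not emulate.

## Worked example

Run the full pipeline on the packaged demonstration conditions (40
synthetic patients, 47 slides of 8×8 tiles at 64 px, planted hazard
ratio 4):

```python
from pannetrisk.orchestration import demo_config, run_pipeline, write_report

result = run_pipeline(demo_config(seed=1))
print(write_report(result))
```

Key lines of the report (abridged):

```
patient-level classification metrics:
  accuracy: 0.8000
  sensitivity: 0.7500
  specificity: 0.8125
  balanced_accuracy: 0.7812
  median_cancer_jaccard: 1.0000
  n_high_risk: 12
  n_low_risk: 28
survival analysis:
  planted_logrank_p: 0.04826
  logrank_p: 0.17407
  risk_group_hr: 1.68829
```

Reading these numbers: the tissue classifier's whole-slide cancer
annotation matches the ground-truth polygons perfectly on these highly
separable synthetic textures (median Jaccard 1.0); the nested LOOCV risk
model recovers the planted metastasis texture effect well above chance
(balanced accuracy 0.78 where 0.5 is chance); the planted hazard ratio
is log-rank detectable in this cohort draw (p = 0.048); and the
predicted risk groups separate survival in the right direction
(HR 1.69) but without significance — at 40 patients the risk-group
log-rank runs close to its power limit (`docs/methods.md` discusses
this).

The same stages are exposed individually (`synthgen`, `tiling`,
`tissue_classifier`, `met_classifier`, `slide_features`, `risk_models`,
`eval_survival`) and through a CLI:

```bash
pannetrisk synth --seed 1 --out synth_out      # cohort CSV + example slide
pannetrisk run-all --seed 1 --out pipeline_out # full pipeline + report
pannetrisk schema                              # 150-feature registry JSON
```

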