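# dermxai

Saliency-map explainability for melanoma classifiers, graded against the
dermoscopic **ABC rule**.

## The problem

When a convolutional network classifies a pigmented skin lesion as melanoma,
dermatologists want to know *whether the model attends to the features they
themselves use*: **A**symmetry of the lesion, **B**order irregularity, and
**C**olor heterogeneity. A reader study posed exactly this question: two
dermatologists graded 100 melanoma dermoscopy images and, separately, the
saliency maps of five visual explanation techniques — Grad-CAM, Grad-CAM++,
Eigen-CAM, Score-CAM, and LIME — on a semi-quantitative 0–2 scale per
criterion, and classified each (clinical grade, map grade) pair by the
absolute difference: 0 = total, 1 = partial, 2 = no agreement.

This package re-implements that evaluation as a fully automated, tested
pipeline:

* **five saliency methods** computed from their defining equations against a
  pluggable classifier adapter (a small numpy fixture CNN with hand-derived
  backprop ships for oracle testing);
* **algorithmic surrogates** for the ABC grading of lesion images and of
  saliency maps, with every rubric threshold explicit and frozen;
* **a synthetic lesion generator** with controllable asymmetry (quadrant
  dissimilarity), border irregularity (perturbed arc fraction), and color
  heterogeneity (1–3+ pigment colors), providing ground-truth grades the
  graders must recover;
* **the agreement statistic** — per-pair classification, confusion matrices,
  the per-technique agreement table, combined total+partial rates, and the
  technique ranking — validated against the reader study's printed counts.

## The statistic at its core

For each technique *t* and criterion *k* ∈ {A, B, C}, grade pairs
(c, m) ∈ {0,1,2}² are tallied by |c − m| into counts
(n_total, n_partial, n_none); pairs with an off-canvas border (NA) are
excluded, shrinking that criterion's denominator. The headline number per
technique is the combined rate

    combined(t) = 100 · (n_total + n_partial) / n  over all three criteria.

The CAM-family maps are L = ReLU(Σₖ αₖ Aᵏ) over the activation maps Aᵏ of a
chosen convolutional layer, with channel weights αₖ given by the spatial
mean gradient (Grad-CAM), the positive-partial-derivative closed form
(Grad-CAM++), or masked forward-pass score differences (Score-CAM);
Eigen-CAM projects the activation matrix on its first right singular vector
(no ReLU, class-agnostic). LIME fits a locally weighted ridge surrogate
over binary superpixel perturbations.

## Worked example

The agreement arithmetic on the reader study's printed counts:

```bash
dermxai report --quiet
```

prints (abridged):

```json
{
 "combined_rates": {"grad_cam": 93.6, "lime": 89.8, "grad_cam_pp": 88.0,
                    "eigen_cam": 86.4, "score_cam": 84.6},
 "ranking": ["grad_cam", "lime", "grad_cam_pp", "eigen_cam", "score_cam"],
 "denominators": {"asymmetry": 200, "border": 190, "color": 200, "TOTAL": 590},
 "errata": [{"technique": "lime", "criterion": "border", "class": "none",
             "printed_pct": 6.84, "computed_pct": 16.84, "known_erratum": true}]
}
```

Grad-CAM leads with a 93.6% combined total+partial agreement rate; the
border denominator is 190 because 10 of the 200 border pairs were NA. The
single erratum flag marks a published percentage (6.84%) that disagrees
with its own count (32/190 = 16.84%); the counts themselves are
internally consistent.

The full synthetic pipeline is driven by the numbered scripts under
`analysis/` (or the equivalent `dermxai synth/explain/grade/agree` CLI):

```bash
python analysis/01_simulate_cohort.py      # 30 lesions, seed 0
python analysis/02_explain_lesions.py      # 150 saliency maps
python analysis/03_grade_lesions_and_maps.py
python analysis/04_agreement_report.py
```

On this cohort (seed 0) the run prints a denominator block of 60/52/60
(four of 30 lesions are off-canvas, so 26 × 2 graders = 52 border pairs)
and combined rates such as `grad_cam_pp: 95.3`, `eigen_cam: 94.2`,
`grad_cam: 84.9` — the *fixture* classifier is a small random CNN, so
these rates characterize the pipeline, not any clinical model. Outputs
land under `results/study/`: grade CSVs, the agreement table, one
confusion-matrix CSV per technique × criterion, and `summary.json`.

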