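# psrquant

Quantification of liver scarring from picrosirius-red (PSR) stained
sections, and how staining variation breaks it.

Collagen proportionate area — the percentage of tissue staining PSR
positive,

```
CPA% = 100 · n_PSR / (n_PSR + n_tissue + n_lumen)
```

— is the continuous measure of fibrosis that clinical trials want instead
of ordinal stages. It is computed from colour, so it inherits every source
of colour variation: which laboratory stained the slide, which batch of
reagents, how long the cut section sat before staining. `psrquant`
implements the two standard computational scorers — a fixed
hue/saturation/brightness (HSB) colour threshold and a trainable four-class
pixel classifier (space / lumen / PSR / tissue; local window statistics +
random forest) in three training regimes (per stain set, combined across
sets, and combined with divergence-targeted retraining) — together with a
synthetic cirrhotic-section generator whose staining model (two
laboratories × two batches, hue/saturation/brightness shifts, section-age
fade, per-slide jitter) lets the whole inter/intra-laboratory consistency
analysis run on a desktop with known ground truth standing in for
stain-free SHG/TPEF imaging.

The audience is anyone building or evaluating stain-based morphometry:
the package shows, reproducibly, how much consistency each method loses to
staining variation and why a stain-free reference does not.

## Worked example

```python
from psrquant import pipeline
from psrquant.synth import StudyDesign

design = StudyDesign(n_cases=20, tile_size=160, master_seed=1, image_format="png")
scores = pipeline.run_full_study(design, "results/study", n_trees=60)
report = pipeline.analyze_scores(scores)

from psrquant.stats import report_frames
pairs, summary = report_frames(report)
print(summary[["method", "median_intra", "median_inter", "reference_rho"]].round(2))
```

prints (seed 1):

```
         method  median_intra  median_inter  reference_rho
0           HSB          0.72          0.62           0.92
1      PIXCLF_i          0.74          0.80           0.88
2     PIXCLF_c1          0.83          0.82           0.92
3     PIXCLF_c2          0.91          0.89           0.97
4  GROUND_TRUTH          1.00          1.00           1.00
```

Read it row by row: per-case scores from the same sections, re-stained,
should rank identically (Spearman ρ = 1). The fixed HSB threshold —
calibrated once on the E1 set, applied to all four sets, the
single-threshold protocol — drops to ρ ≈ 0.6 between laboratories.
Classifiers trained per stain set (`PIXCLF_i`) fare little better; one
classifier trained across all sets (`PIXCLF_c1`) is more consistent;
retraining it on the cases whose inter-laboratory scores diverged more
than 2× (`PIXCLF_c2`) helps again; and the stain-free scorer is immune.
`reference_rho` — the correlation with true scar fraction — ranks the
same way. Single-seed ρ estimates on 20 cases are noisy (here the
per-set classifier's intra value dips below its inter value); the
acceptance run below repeats the study over seven master seeds and takes
medians, where every computational method is at least as consistent
within a laboratory as between laboratories.

The numbered drivers under `analysis/` run the same pipeline as a
narrative: `01_simulate_study.py` (generate the study),
`02_score_methods.py` (score every slide with every method),
`03_consistency_analysis.py` (pair correlations, summaries, boxplot),
`04_stain_drift_degradation.py` (fixed-threshold error versus hue drift),
`05_section_age_effect.py` (the fresh-restain rN3 comparison). Outputs
land under `results/`.

A `psrquant` console script wraps the same three stages
(`simulate` / `score` / `analyze`) over a YAML config; see
`psrquant show-defaults`.

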