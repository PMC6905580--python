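# sdmfusion

Species distribution modelling from sparse, mixed-quality data: fuse
ground-survey records, thermal-imagery detections and expert-elicited
habitat judgements into one coefficient vector with honest uncertainty.

## The problem

Monitoring rare or cryptic species (the motivating case is the koala, an
arboreal folivore that even trained observers miss) rarely yields enough
clean presence/absence data for a reliable species distribution model
(SDM). Three partial information sources are typically available:

- **ground surveys** — trustworthy sightings, but biased toward accessible
  places (paths, open areas);
- **aerial thermal imagery** — spatially unbiased detections, but each
  hotspot carries a detection-algorithm confidence below certainty;
- **expert judgement** — structured elicitation of habitat-suitability
  probabilities, each with the expert's own stated confidence.

`sdmfusion` implements a pipeline that uses all three, down-weighting each
record by its confidence instead of discarding uncertain data.

## The model

All models share a logit-linear predictor on six standardized habitat
covariates (longitude, latitude, foliage projective cover, remnant
food-tree vegetation, distance to path, distance to water), centred and
scaled by the moments of the base ground-survey data so coefficients are
commensurate.

1. **Survey models (G, GT).** Weighted logistic regression maximizing
   `Σᵢ wᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]`, `pᵢ = expit(xᵢ'β)`, with
   confidence weights `wᵢ` (1.00 ground sighting; 1.00/0.90/0.50 thermal
   classes; 0.90 for randomly generated absences).
2. **Expert model (E).** Weighted Beta regression with a Gaussian random
   intercept per expert: `y_ij ~ Beta(μ_ij φ, (1−μ_ij) φ)`,
   `logit(μ_ij) = xᵢ'β + u_j`, `u_j ~ N(0, σ²)`, fit by marginal maximum
   likelihood with adaptive Gauss–Hermite quadrature; weights 0.50/0.75/1.00
   encode stated confidence.
3. **Fusion (G_E, GT_E).** Elementwise inverse-variance pooling:
   `β̂_c = (β_o s_o⁻² + β_e s_e⁻²)/(s_o⁻² + s_e⁻²)`,
   `s_c² = (s_o⁻² + s_e⁻²)⁻¹`, with t intervals on `v_c = v_o + v_e`
   residual degrees of freedom.
4. **Evaluation.** High-confidence thermal records (weight ≥ 0.90) form the
   validation set; GT/GT_E predictions use leave-one-out refitting;
   probabilities ≥ 0.4 classify as presence; accuracy, sensitivity,
   specificity and RMSPE (on raw probabilities) summarize performance.

A first-class synthetic-data module (`simulate_study` and friends)
generates landscapes, biased surveys and expert panels with this exact
structure, so the whole pipeline is testable without field data. An
elicitation-design module (Gower distance + hierarchical clustering)
reproduces the image-subset selection shown to experts.

## Worked example

```python
import sdmfusion as sf

data = sf.simulate_study(seed=1)          # landscape + surveys + experts + grid
result = sf.run_study(data.observations, data.covariates,
                      data.elicitations, data.grid)
print(result.report_table().round(3).to_string(index=False))
```

prints

```
model  accuracy  sensitivity  specificity  rmspe
    G     0.650        0.882        0.478  0.476
   GT     0.825        0.941        0.739  0.395
  G_E     0.775        1.000        0.609  0.367
 GT_E     0.775        1.000        0.609  0.361
```

Each row evaluates one recipe on the 40-record high-confidence validation
set: the ground-only G model misclassifies a third of the sites and has the
largest probability error (RMSPE 0.476), while every recipe that adds
thermal and/or expert information classifies better and predicts sharper —
the fully fused GT_E model reaches perfect sensitivity with the smallest
RMSPE. `result.combined["GT_E"].coef_table()` shows the fused coefficients
with 95% t intervals (in this simulation the negative `dist_water` effect —
koalas concentrating near the river — is recovered and significant), and
`result.predictions` holds the four probability surfaces over the 636-site
grid, ready for mapping. The `examples/` scripts walk through each stage
separately.

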