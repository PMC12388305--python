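# sakemet

Predicting sensory panel scores of Japanese sake from untargeted LC-MS
metabolome peak tables with single-response OPLS regression.

Sake flavor is scored by trained panels using quantitative descriptive
analysis (QDA): each sample is rated on bounded line scales (sweetness,
sourness, body, fruity *ginjo*-type aroma, overall quality, ...) over
several rounds. In parallel, UPLC-Q/TOF-MS profiling of the same samples
yields a peak table — injections × detected features with retention-time
and m/z metadata. `sakemet` implements the full analysis chain that links
the two:

1. **Peak-table preprocessing** — remove features whose maximum intensity
   is zero, then features whose replicate coefficient of variation reaches
   10% in any sample; annotate survivors against an in-house compound
   library within 0.1 min / 0.007 Da; optionally merge general-property
   columns (acidity, aroma compounds) as extra variables.
2. **Sensory QC** — per (sample, attribute) box-whisker outlier removal
   (Tukey fences, single pass), a one-way ANOVA gate (attributes that do
   not discriminate between samples at α = 0.05 are dropped), and sample
   means.
3. **Chemometrics** — UV (auto)scaling, PCA overview, and a NIPALS OPLS
   estimator for a single response: one predictive component plus *k*
   X-orthogonal components, written `1 + k + 0`. Cross-validation is
   replicate-aware: all injections of a sample share a fold (7-fold), so
   Q² = 1 − PRESS/SS is not inflated by replicate leakage.
4. **Model building** — the orthogonal-component count is the largest for
   which Q² still increases; the configuration is then validated by a
   permutation test (n = 100, y re-assigned across samples) with the
   R²-intercept < 0.3 / Q²-intercept < −0.05 criteria, removing components
   until it passes; CV-ANOVA gives a model p-value; variable importance is
   **signed VIPpred** (VIP over the predictive component, signed by the
   Pearson correlation with the attribute's sample means), with selection
   at VIPpred > 1.5.
5. **Transfer validation** — a model fitted on one year is applied
   unchanged to another year (target scaled with the training model's
   parameters); variables with |signed VIPpred| > 1.5 in *both* years
   define reduced models that are refitted and cross-validated again.

A first-class **synthetic-data generator** reproduces the statistical
structure this analysis assumes — triplicate injections with controlled
replicate CVs, planted filter targets, factor-structured peak
correlations, bounded panel noise, injected score outliers — with known
ground truth, so the whole pipeline can be verified end to end.

## Worked example

```python
from sakemet import GeneratorConfig, AnalysisParams, simulate_and_run

dash = simulate_and_run(GeneratorConfig(seed=3), params=AnalysisParams(seed=3))
print(dash["filters_exact"], dash["n_retained_peaks"])   # True 430
print(dash["outliers_exact"])                            # True
print(dash["attributes"]["sweetness"])
```

prints (seed 3):

```
True 430
True
{'latent_variables': '1 + 2 + 0', 'r2': 0.9822, 'q2': 0.9726, 'rmse': 0.0888,
 'n_selected': 53, 'cv_anova_p': 1.9e-90, 'permutation_valid': True,
 'driver_recovery': 1.0, 'sign_agreement': 1.0}
```

Reading: the two filters reduced the 455 exported peaks to exactly the 430
informative ones; box-whisker QC removed exactly the injected outlier
scores; the sweetness model used one predictive and two orthogonal
components with R² 0.98 and cross-validated Q² 0.97 (RMSE 0.09 score
units), survived the permutation test, selected 53 of 430 peaks at
VIPpred > 1.5, and all five planted driver peaks were recovered with the
correct correlation sign.

The same steps are available on CSV inputs from the command line:

```bash
sakemet simulate --seed 3 --out data/
sakemet preprocess --peaks data/peaks.csv --library data/library.csv \
        --out filtered.csv --report filters.json
sakemet sensory-qc --panel data/panel.csv --scales data/scales.yaml \
        --out clean.csv --anova anova.csv
sakemet run-all --peaks data/peaks.csv --panel data/panel.csv \
        --library data/library.csv --seed 17 --out results/
```

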