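# tractmix

Quantitative profiling of white-matter tract injury from diffusion-tensor
MRI, built for small, severely affected patient cohorts — the motivating case
is locked-in syndrome (LIS), where a focal ventral pontine lesion coexists
with diffuse white-matter damage that conventional morphological MRI misses.

The pipeline answers the question *which of the 48 JHU-atlas white-matter
tracts are the most injured in this patient group?* in four stages:

1. **DTI metrics** — per-voxel diffusion tensor by log-linear least squares,
   then the four scalar coefficients FA, MD, AD, RD from the eigenvalue
   spectrum (MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2,
   FA = √(3/2)·‖λ−MD‖/‖λ‖), averaged per atlas tract over a white-matter
   skeleton mask to avoid grey-matter partial volume.
2. **Normative Z-scores** — each patient's tract mean standardised against a
   control cohort: Z = (x − μ̂_ctrl)/σ̂_ctrl, with |Z| > 1.96 as the
   single-subject abnormality flag.
3. **Bayesian mixture classification** — tracts (not subjects) are the
   statistical units. The bivariate (FA, MD) Z-scores of tract *b* in
   subject *j* follow a two-component Gaussian mixture with a per-tract
   random effect:

   x_bj | z_b, a_b ~ N₂(μ_{z_b} + a_b, Σ),  a_b ~ N₂(0, diag(σ₁², σ₂²)),
   P(z_b = 1) = p

   with conjugate priors (p ~ Beta(1,2); μ coordinates ~ N(0, 1000);
   σ² ~ Inv-Gamma(100,100); Σ⁻¹ ~ Wishart, vague). A Gibbs sampler with the
   random effect integrated out of the membership update yields each tract's
   posterior probability of belonging to component 2 — the *most injured*
   group, identified by an ordering constraint on the component means. A
   tract is classified group 2 when that probability strictly exceeds 0.5.
4. **Reporting** — ranked Z-score tables, probability and binary affiliation
   maps painted back onto the atlas volume, prior-sensitivity analysis, and
   machine-readable run reports with seed and config-hash provenance.

A synthetic-cohort generator reproduces the study design (48 tracts × 7
patients × 19 controls, occasional missing cells) with known ground truth, so
every stage is testable without patient data. The package also bundles the
published per-tract Z-scores of one patient as a real-data fixture.

## Worked example

```python
import tractmix as tm

cfg = tm.CohortSimConfig(seed=42)                 # study-shaped defaults
zscores, truth = tm.simulate_zscore_cohort(cfg)   # 48 tracts x 7 patients

model = tm.TractMixture(n_chains=4, n_iterations=5000,
                        burn_in=1000, random_state=0).fit(zscores)
print(model.posterior_.sort_values("prob_group2", ascending=False).head(6))
```

prints

```
                                 tract  prob_group2  mc_se  label
Superior fronto-occipital fasciculus R        1.000  0.000      2
                    Medial lemniscus R        0.998  0.000      2
        Superior cerebellar peduncle L        0.968  0.002      2
                    Medial lemniscus L        0.955  0.003      2
               Genu of corpus callosum        0.366  0.002      1
            Cingulum cingulate gyrus L        0.238  0.004      1
```

`prob_group2` is the posterior probability that the tract belongs to the
most-injured component, `mc_se` its Monte-Carlo standard error across chains,
and `label` the >0.5 classification. Here the four tracts simulated as most
injured (both medial lemnisci, the right superior fronto-occipital fasciculus
and the left superior cerebellar peduncle) are recovered exactly — 100%
agreement with the simulated truth.

The same analysis runs end to end from the shell:

```bash
tractmix run-all --out run1 --seed 42
tractmix fit --zscores cohort_FA_MD.xlsx --out fit1 --seed 0   # deposited-style workbook
```

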