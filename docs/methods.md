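# Methods

## Statistical model

Tracts are the statistical units. For tract *b* (of *B*, nominally 48) and
subject *j* (of *J*, nominally 7), the bivariate observation
x_bj = (Z_FA, Z_MD) follows

    x_bj | z_b, a_b  ~  N₂(μ_{z_b} + a_b, Σ)
    a_b              ~  N₂(0, D),  D = diag(σ₁², σ₂²)
    P(z_b = 1) = p,  P(z_b = 2) = 1 − p

Component 1 collects the least-injured tracts, component 2 the most injured.
The per-tract random effect a_b models intra-bundle variability — the stable
deviation of a tract from its component mean, shared across subjects — while
Σ captures residual subject-to-subject variation. Both D and Σ are shared by
the two components; the model is deliberately exchangeable in the component
labels except for the ordering constraint below. Tract–subject cells missing
either coordinate are dropped as whole bivariate observations; a tract with
no complete observation is excluded with a warning (reports keep it in the
excluded count so group-1 + group-2 + excluded always totals the atlas size).

### Priors

* p ~ Beta(1, 2) — low-information, mildly favouring a smaller group-1
  weight a priori.
* Each coordinate of μ₁, μ₂ ~ N(0, 1000) — effectively flat on the Z-scale.
* σ₁², σ₂² ~ Inverse-Gamma(100, 100). This prior concentrates near 1, the
  natural unit for Z-scored data. The notation it was transcribed from is
  ambiguous (a "(100,100)" pair with no named family), so the shape/rate pair
  is exposed in the configuration and varied in the sensitivity analysis
  rather than treated as settled.
* Σ⁻¹ ~ Wishart with df = 2 (the minimum for dimension 2; configurable) in
  the BUGS `dwish` rate convention: the prior contributes R₀ = 10⁻⁴·I to the
  posterior sum of squares, i.e. it is vague relative to the ≳300
  observations of a study-sized fit. The convention matters: reading the same
  "0.0001" as a scipy-style scale matrix makes the prior contribute 10⁴·I —
  equivalent to two phantom observations of magnitude 100 — which drives the
  posterior residual variance to ≈30 on Z-scale data and collapses the
  mixture. Only the rate reading is consistent with a fit in which the data
  dominate the prior.

### Gibbs sampler

All full conditionals are conjugate. Per iteration:

1. **z_b** — *blocked* update with the random effect integrated out:
   marginally x̄_b ~ N₂(μ_k, Σ/n_b + D) for component k, where x̄_b and n_b
   are the tract's observed mean and count. Sampling z from this marginal and
   then a_b | z_b from its exact conditional is a valid blocked Gibbs kernel
   for the same posterior. The naive update of z conditional on the current
   a_b is catastrophically sticky here: a_b absorbs the tract's location, the
   component means merge, and every membership probability collapses toward
   the prior. The blocked kernel compares components on the correct
   between-tract scale (D + Σ/n_b) and mixes well.
2. **p | z** ~ Beta(1 + n₁, 2 + n₂).
3. **a_b | rest** ~ N₂ with precision D⁻¹ + n_b Σ⁻¹ (degenerate D = 0 maps
   to a_b = 0).
4. **μ_k | rest** ~ N₂ combining the N(0, 1000·I) prior with the component's
   observations (an empty component draws from its prior).
5. **σ_d² | a** ~ Inverse-Gamma(100 + B/2, 100 + ½Σ_b a_bd²).
6. **Σ⁻¹ | rest** ~ Wishart(df₀ + N_obs, (R₀ + SSE)⁻¹), sampled by Bartlett
   decomposition.
7. **Relabeling** — if the drawn means violate the constraint
   sum(μ₂) ≤ sum(μ₁), components are swapped (μ, z, p → 1−p). This pins
   component 2 to the semantically "most injured" (more negative mean sum)
   side in every retained draw and removes label switching from the
   membership probabilities.

Membership probability per tract is the fraction of retained draws with
z_b = 2; its Monte-Carlo SE is the between-chain SD of that fraction over
√C (binomial/ESS-based for a single chain). Classification is strict:
label 2 iff probability > 0.5, ties to group 1. Convergence is monitored by
split-chain R-hat and bulk ESS (via arviz) on p, the μ coordinates, the
random-effect SDs and the Σ elements; R-hat > 1.1 on p or μ attaches a
warning to the draws, never silently.

Defaults: 4 chains × 20,000 iterations, burn-in 5,000, thinning 1, per-chain
seeds spawned from one master seed. The unit and acceptance tests run
reduced budgets (1–4 chains × 300–8,000 iterations) chosen so the checked
quantities' Monte-Carlo error is comfortably below the asserted tolerances;
a study-sized fit at the default budget takes on the order of a minute on
one CPU core.

### Sensitivity analysis

`sensitivity_analysis` refits the model over a grid of prior settings
(default: Wishart rate 10⁻⁵…10⁻²; random-effect prior hyperparameters can be
varied the same way) and reports per-tract label agreement with the baseline
fit. Failures at a grid point are recorded in the output table rather than
aborting the grid. On well-separated data the classification is invariant
across the grid — the behaviour expected when the data dominate the priors.

## DTI metrics stage

The tensor is estimated by ordinary (unweighted) log-linear least squares on
ln S = ln S₀ − b·gᵀDg; a signal-weighted variant sits behind a flag. Voxels
with any non-positive signal are flagged invalid rather than fitted. The
design must contain a b=0 volume and have full column rank (≥6 non-collinear
directions); rank deficiency raises. Negative eigenvalues are clamped to 0
before the scalar metrics, and the FA of an all-zero spectrum is defined as
0 (isotropy convention for empty voxels). ROI means are taken over voxels
with the tract's atlas label AND skeleton membership; tracts contributing
fewer than `min_voxels` (default 5) skeleton voxels are recorded missing,
never as 0. Volumes must share a grid — registration is assumed done
upstream, and the affine is carried through unchanged to output maps.

## Z-scoring stage

The control reference uses the sample SD (n−1); cells with zero control SD
are flagged degenerate and propagate to missing, as do missing patient
inputs. No small-sample t-correction is applied: ±1.96 is used as a Gaussian
cutpoint with strict inequality, matching normative single-subject practice
for this design. With a large control group, null patients exceed |Z| > 1.96
in ≈5% of cells; with only 19 controls the true exceedance rate is slightly
higher (heavier-than-Gaussian tails of the studentised score) — the
calibration test therefore uses 500 controls, where the nominal rate holds.
Ranked per-patient tables list the most negative Z first, missing entries
last, mirroring the published table layout.

## Synthetic cohort generator

The generator *is* the study design: 48 JHU-atlas tracts × 7 patients × 19
controls, bivariate (FA, MD) Z-scores drawn from the mixture model above,
cells masked completely at random at rate 0.02 (the deposited workbooks mark
occasional cells uncomputable). Group-2 defaults are the four tracts
classified most-injured in the reference cohort (both medial lemnisci, right
superior fronto-occipital fasciculus, left superior cerebellar peduncle).
Default means μ₁ = (−5.5, −6.5) and μ₂ = (−9.5, −8.5) are the groupwise
averages of the bundled single-patient fixture, with σ₁ = σ₂ = 1 and Σ = I —
deliberately *moderate* separation: at these conditions a group-1 tract with
an unlucky random effect can genuinely resemble group 2, so graded
probabilities (not saturated 0/1 assignments) are the expected behaviour,
as in the reference cohort. Raw-metric tables use a fixed normative ramp of
physiologically plausible FA/MD/AD/RD values per tract, so standardising the
simulated patients against the simulated controls recovers the configured
mixture within sampling error (tested end to end).

The voxel phantom fills slab-shaped atlas regions with template tensors,
synthesises diffusion-weighted signals S = S₀·exp(−b·gᵀDg) over a Fibonacci
direction scheme (30 directions, b = 1000 s/mm² by default), and draws a
random skeleton subset of labeled voxels. It emulates the *shape* of imaging
input, not its physics: no anatomy, lesion geometry, registration error,
Rician noise floor, or eddy/motion artefacts. Passing phantom tests shows the
voxel-to-table plumbing is correct, not that the pipeline is robust to real
acquisition artefacts.

## Design choices that were genuinely open

* **Random-effect indexing** — the printed model has two component-level
  random vectors A₁, A₂, while the accompanying text attaches the effect to
  the nerve bundle. One a_b per tract, applied to whichever component the
  tract occupies, is implemented: it is the only reading that gives the
  effect its stated job (intra-bundle variability repeated across subjects).
* **Identifiability** — no ordering constraint is stated upstream; the
  more-negative-mean-sum rule is adopted because it matches the semantic
  definition of the injured group.
* **Missing bivariate cells** — whole-observation deletion rather than
  single-coordinate imputation; the simplest coherent treatment, and the
  missingness rate is small.
* **Artefact flagging** — tracts whose group-2 assignment is anatomically
  suspect (the superior fronto-occipital fasciculi, whose ROIs misalign onto
  atrophied ventricles during registration) are annotated in run reports,
  never removed: the flag is metadata, the classification stands.

## Limitations

* The mixture assumes exactly two components with shared Σ and D; no model
  comparison is provided.
* MCAR missingness is an assumption of convenience; the true mechanism of
  uncomputable cells (noise) is plausibly informative.
* The pipeline consumes pre-aligned volumes and a precomputed skeleton mask;
  eddy/motion correction, brain extraction, nonlinear registration and the
  TBSS skeleton projection are out of scope.
* Normative Z-scores from 19 controls carry non-trivial estimation noise in
  σ̂_ctrl (≈16% relative), which propagates multiplicatively into every Z; the
  mixture operates on, and its probabilities reflect, that noisy scale.
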