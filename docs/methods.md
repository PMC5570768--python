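# Methods

This note records the models, algorithms and numerical choices behind
`metabatch`, in the order the pipeline applies them.

## Multivariate characterization and DOE selection

Samples described by K clinical/personal descriptors are summarized by a
two-component PCA score map.  Categorical descriptors are one-hot encoded;
columns constant within the modelled group are dropped (they carry no
selection information).  Scores are computed per group, so each group's
selection spans that group's own variability.

A full two-level factorial design is fitted into the (t1, t2) plane: four
corners at (±w₁, ±w₂) plus the center (0, 0).  The half-widths w_j are
either the q-quantile of |t_j| (`quantile` mode, default q = 0.95) or a
multiple of sd(t_j) (`sd` mode).  The default is a compromise between a
"small square" that excludes outliers (pilot studies) and a "wide square"
that covers the full observed variation; both are exposed.  Selection
visits the design points in the fixed order (−,−), (−,+), (+,−), (+,+),
center, assigning each point its quota of nearest unassigned samples by
Euclidean distance on the raw scores (components are already
variance-ordered, so no re-standardization).  Distance ties break by
sample-id lexicographic order, making the selection platform independent.
A group smaller than the design emits a warning and is taken in full.

Batch allocation reuses the same machinery by *iterative peeling*: within
each group, batch 1 receives a miniature representative selection of its
target size (design points visited round-robin, nearest remaining sample
each time), batch 2 selects from what remains, and the last batch takes the
remainder.  Targets are ⌊n_g/B⌋ or ⌈n_g/B⌉, so a 23-sample group over four
batches contributes (6, 6, 6, 5) in some order.  The original group scores
are reused for every peel (a `refit_pca_per_batch` switch refits them if
desired; the default avoids re-deriving the map from ever-smaller subsets).

## NIPALS PCA

Components are extracted sequentially with deflation.  The score/loading
regressions run over observed cells only, so missing descriptor values
(capped at 50 % per column) need no imputation.  Convergence: relative
score change below 1e−10, iteration cap 100 000.  The cap is deliberately
generous — NIPALS is a power iteration whose convergence rate is the ratio
of adjacent eigenvalues, and noise-like matrices (as arise inside
cross-validation folds) can need tens of thousands of the very cheap
iterations at the matrix sizes this package targets.  Complete-data fits
use a plain matrix-product fast path.

Per-component explained variation is R²X_a = ‖t_a p_aᵀ‖² / ‖X‖² on the
scaled matrix.  Cross-validated Q² uses row-wise sevenfold groups
(round-robin on input order, i.e. every-Nth-sample; a seeded shuffle is
optional).  For each left-out row, each cell is predicted from the *other*
cells of that row through the training loadings (the score used for cell k
excludes cell k).  This leave-one-cell-out prediction removes the
self-prediction bias of naive row projection, which would credit a
K-column noise matrix with Q² ≈ 1/K; with it, pure noise scores Q² ≤ 0 as
it should.  Q²_a = 1 − PRESS_a/SS_{a−1}, pooled over folds.  A component is
retained when Q² > 0.05, with a hard cap (default 2) to avoid over-fitting;
model fitting can also be run with a fixed component count (used, e.g., for
the one-component IS normalization model).

## Scaling and internal-standard normalization

Column scaling modes: UV (center, divide by sample sd, ddof = 1), UVN
(divide by sd only, no centering — keeps nonnegative data nonnegative),
CENTER, NONE.  Fitted means/sds are stored so the identical transform can
be replayed on new rows.  Zero-variance columns are rejected by name.

IS normalization fits a one-component PCA to the UVN-scaled internal
standard sub-matrix and divides every channel of sample i (IS and
metabolites) by its t1 score.  Because the data are uncentered and t1 is a
linear projection, a per-sample multiplicative factor (injection volume,
detector sensitivity) cancels exactly.  t1's sign is fixed by requiring a
positive mean — IS areas are strictly positive, so the dominant component
is single-signed and the orientation makes the division well defined.
Samples with non-positive or zero-|t1| (< 1e−12) IS signals are rejected by
id.  Note that the *absolute scale* of the normalized matrix depends on the
fitted model (the UVN sds and loading norm), so normalized matrices are
meaningful up to a model-wide constant; all downstream models are scale
invariant, so this is immaterial.  Normalization is fitted per batch by
default (the per-day workflow); a single global fit is a switch.  Missing
values in non-IS columns pass through as missing.

## OPLS and OPLS-DA

Single-response OPLS, components "1 + A_o + 0" (one predictive, A_o
X-orthogonal, no Y-orthogonal; only single-Y models are implemented).  For
each orthogonal component: w ∝ Xᵀy normalized, t = Xw, p = Xᵀt/tᵀt,
w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o, deflate X ← X − t_o p_oᵀ.
The predictive component is then recomputed on the deflated matrix.  The
default is one orthogonal component, matching the two-component cap.

For discriminant analysis the response is a 0/1 class dummy, centered (and
scaled to unit variance, which only affects the inner-relation coefficient,
not scores or loadings).  The positive class defaults to the
lexicographically larger label and is configurable; positive p(corr) then
means "more abundant in the positive class".  The run-order diagnostic is
the same machinery with the injection index as a continuous response,
1 + 1 components; the reported effect is the predictive component's percent
of X variation, invariant to affine increasing relabelings of the order.

p(corr)ₖ is the Pearson correlation between the predictive score t and the
*original* scaled column k (before orthogonal deflation).  It is bounded in
[−1, 1] and invariant to positive per-column rescaling under UV scaling.

### Cross-validation and jackknife

Folds are assigned round-robin within each class in input order (stratified;
a seeded shuffle is optional), guaranteeing both classes in every training
split; folds left empty by small classes are dropped and N is the number of
nonempty groups.  Each sub-model refits scaling on its training rows.  Q²
pools the class-dummy PRESS over folds against the training-mean reference.

The precision of each p(corr) is the classical delete-one-group jackknife
over the N sub-models: SEₖ = √((N−1)/N · Σᵢ(θᵢₖ − θ̄ₖ)²).  Commercial
chemometrics software computes an internally defined (undocumented)
variant; the classical estimator is used here and documented as such.
Before pooling, each sub-model's score sign is aligned with the full model
(t has an arbitrary sign; an accidental flip would inflate the spread).
The per-batch confidence interval is t(1 − α/2, N − 1) · SE with α = 0.05.

## Multi-batch integration

Given B ≥ 2 batches over the identical metabolite set: a metabolite is
*sign-consistent* when its p(corr) carries the same strict sign in every
batch (an exact zero has no sign and fails the filter — a deliberate strict
reading).  Averages are arithmetic means over batches, defined only where
consistent.  Standard errors combine as the root mean square
SE_avg = √(Σ_b SE_b²/B); the combined interval is t(1 − α/2, N_total − B) ·
SE_avg, where N_total counts cross-validation groups over all batches (one
degree of freedom per batch).  With three sevenfold batches this is the
t-quantile at 18 df.  Significance is the strict inequality
|avg p(corr)| > CI.  SUS-plot data report paired p(corr) values, a
same-direction mask and the squared Pearson correlation (the coefficient of
determination of the simple regression line).  Combined CIs are computed
for every sign-consistent metabolite.

## Synthetic data

The generator emulates, on the log scale, the nuisance structure the
pipeline assumes: for metabolite k of sample i in batch b at (scaled) run
position r,

log x = baseline_k + effect_k·case_i·σ + shift_bk + scale_bk·z_i
        + slope_b·d_k·r + ε,   ε ~ N(0, σ²),

exponentiated and multiplied by the sample's injection factor
exp(N(0, σ_inj²)), which also multiplies the IS channels.  IS channels
carry baseline, drift, (smaller) noise and the injection factor but no
biology; their drift sensitivity is centered at 0.4 versus 1.0 for
analytes, because spiked, chemically stable standards track sensitivity
drift more weakly than analytes — this is what leaves a detectable
run-order effect after normalization, as observed in practice.

Defaults mirror a mid-size clinical study: 5 disease subgroups + controls,
23 samples per group, 205 descriptors, 73 metabolites, 11 internal
standards, 4 batches.  Nuisance scales (chosen once, at magnitudes typical
for multi-day GC–MS acquisitions): σ = 0.3, batch shift sd 0.3, batch scale
sd 0.1, drift slope sd 0.2, injection sd 0.2.  Planted case/control effects
default to ±1.5 σ on the first eight metabolites.  Everything is a pure
function of the seed.

What the generator does **not** emulate: peak-detection dropout correlated
with abundance, heteroscedastic detector noise, retention-time-dependent
co-elution artifacts, or correlated metabolite modules.  Passing recovery
tests therefore demonstrate correctness of the *statistical machinery*
under the stated model, not robustness to every failure mode of real
chromatography.

## Recovery behavior (computed by the test suite and acceptance script)

On the bundled three-batch reference table the integration reproduces the
table's own summary columns (42 sign-consistent metabolites; averaged
p(corr) values within rounding of the printed ones; 3 significant
compounds).  On synthetic data: injection factors are removed to machine
precision; pure-noise OPLS-DA yields Q² ≤ 0 in the large majority of
seeded replicates; a drift planted in one batch gives it the largest
run-order effect in ≥ 90 % of seeds; and with 6 + 6 samples per batch over
three batches, ±1.5 σ effects are sign-consistent in > 95 % of seeds while
null metabolites are called significant in well under 10 %.  Problem sizes
in the stochastic suites (n ≈ 35 per batch, K = 73 or smaller, 100 seeds)
were chosen to match the study-scale defaults while keeping the whole suite
desk-scale.

## Known limitations

* Only single-response OPLS (the "+ 0" in the component notation is fixed);
  multi-class designs must be decomposed into pairwise contrasts.
* OPLS requires complete data; rows with missing cells must be imputed or
  dropped upstream (PCA, by contrast, tolerates missingness natively).
* The jackknife SE is the classical delete-group estimator; numerical
  agreement with proprietary implementations is approximate by design.
* Batch allocation assumes every group has at least as many members as
  batches.
* The power knee of the per-batch jackknife CI sits near standardized
  effects of ~1.2 at n = 35 with sevenfold CV: smaller planted effects are
  detected in a minority-to-moderate fraction of replicates per batch
  (sign-consistency across batches, which drives the combined profile, is
  much more sensitive).
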