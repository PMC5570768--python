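# metabatch

Multivariate sample selection and multi-batch integration for metabolomics
profiling.

## The problem

Large clinical cohorts cannot be profiled in one analytical run.  Two
decisions then dominate the quality of a relative-quantification study such
as GC–TOF–MS metabolomics: *which* samples to analyze, and *how* to combine
results acquired in separate batches on different days, when between-batch
instrument drift is often the largest source of variation in the pooled
data.

`metabatch` implements a multivariate strategy for both:

1. **Representative selection.** Samples described by many clinical/personal
   descriptors are summarized by a NIPALS PCA score map (multivariate
   characterization).  A full two-level factorial design — a square with
   four corners plus a center point — is fitted into the (t1, t2) plane and
   the samples nearest each design point are selected (default 5 per corner
   + 3 center = 23 per group).  The same mechanism, applied repeatedly to
   the remaining samples, divides the selection into representative
   analytical batches, so every batch is a miniature of the cohort and can
   be analyzed (or discarded) as an independent study.
2. **Per-batch modelling.** After internal-standard normalization (each
   sample divided by its t1 score from a one-component, uncentered-scaling
   PCA of the IS channels), each batch gets its own OPLS-DA model
   (case vs control, unit-variance scaling, sevenfold cross-validation)
   plus a 1 + 1 OPLS run-order model as a drift diagnostic.
3. **Integration by p(corr), not by data concatenation.** The quantity
   carried across batches is the correlation-scaled predictive loading

   p(corr)ₖ = corr(t, xₖ) ∈ [−1, 1],

   which is invariant to column scaling and therefore comparable between
   models as long as the same variables are used.  Metabolites whose
   p(corr) has the same sign in **all** batches are averaged; per-batch
   jackknife standard errors over the N cross-validation groups,

   SEₖ = √((N−1)/N · Σᵢ (θᵢₖ − θ̄ₖ)²),   CIₖ = t(0.975, N−1) · SEₖ,

   are pooled as SE_avg = √(Σ_b SE_b² / B) with combined interval
   t(0.975, N_total − B) · SE_avg, and a metabolite is significant in the
   combined profile when |average p(corr)| exceeds its combined CI.
   Shared-and-unique-structure (SUS) plot data quantify profile similarity
   between batches.

A seeded synthetic-data module generates cohorts with latent descriptor
structure, planted case/control effects, per-batch location/scale effects,
run-order drift and per-sample injection factors, so the whole pipeline is
testable without any external data.

## Worked example

The package bundles a reference table of per-batch OPLS-DA p(corr) loadings
for 73 identified plasma metabolites from a three-batch case/control study
of systemic lupus erythematosus (SLE):

```bash
python examples/04_integrate_reference_batches.py
```

prints

```
sign-consistent metabolites: 42 of 73
significant in the combined profile: 3
  2-Oxoisocaproic acid: avg p(corr) = -0.580, CI = 0.387
  Ornithine: avg p(corr) = +0.338, CI = 0.323
  Tryptophan: avg p(corr) = -0.336, CI = 0.258
SUS R2 batch 1 vs 2: 0.455
SUS R2 batch 1 vs 3: 0.169
SUS R2 batch 2 vs 3: 0.055
```

42 of the 73 metabolites change in the same direction in all three batches
and form the combined profile; three of them (a branched-chain keto acid
elevated in controls, ornithine elevated in cases, tryptophan lowered in
cases) remain significant after their averaged confidence intervals are
applied.  The low pairwise SUS R² values show the batch profiles share only
weak structure — exactly the situation in which averaging p(corr) vectors,
rather than concatenating drifting raw data, is the safer integration
route.

The other example scripts cover selection/allocation
(`01_select_and_allocate.py`), IS normalization and the run-order
diagnostic (`02_normalize_and_diagnose.py`, where a drift planted in batch
4 yields ~11 % run-order effect against ~4 % in clean batches), a single
batch's OPLS-DA with jackknife CIs (`03_single_batch_oplsda.py`) and the
end-to-end pipeline (`05_full_pipeline.py`).

A thin CLI mirrors the library:

```bash
metabatch simulate --seed 1 --out syn
metabatch select syn/descriptors.csv --out selection.csv
metabatch allocate selection.csv --n-batches 4 --out batches.csv
metabatch fit syn/peak_areas.csv --is-columns IS_01,...,IS_11 --out results
metabatch integrate results/batch_*_results.csv --out combined.csv
metabatch sus results/batch_1_results.csv results/batch_2_results.csv
metabatch run --seed 1 --out full_run
```

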