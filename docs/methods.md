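# Methods

`fabrynet` implements a plasma targeted-metabolomics case/control analysis
for Fabry disease: preprocessing, covariate-adjusted moderated differential
analysis, unsupervised exploration, differential partial-correlation
networks with leave-one-patient-out consensus signatures, and exhaustive
random-forest evaluation of the consensus metabolites.  Because no matching
public dataset is available, every stage is exercised against a synthetic cohort generator that plants known
structure; all empirical statements below are reproduced by the test suite
or by `scripts/acceptance.py`.

## Data model

Concentrations (µM) live in a samples × metabolites table with missing
cells; clinical covariates (group, sex, age, phenotype, treatment, LysoGb3
in ng/mL, residual enzyme activity as a fraction of control) in a
per-sample table; and each metabolite carries one of the p180 reporting
classes (acylcarnitine, amino acid, biogenic amine, glycerophospholipid,
lysophosphatidylcholine, sphingomyelin, hexoses).  Composition summaries
fold lysophosphatidylcholines into glycerophospholipids by default, the
convention used when class totals are reported for this panel; a flag keeps
them separate.  Hexoses (the H1 sum) stay in the analysis matrix — nothing
in the pipeline treats them specially.

## Preprocessing

Fixed order: impute → log → pareto.

* **Imputation** is nearest-neighbour averaging with metabolites as rows:
  a missing cell is replaced by the mean of the k = 10 nearest metabolites
  (Euclidean distance over mutually observed samples) observed in that
  sample; rows more than 50% missing fall back to per-sample means.
  Imputing raw concentrations keeps imputed values positive, so the
  subsequent log is always defined.
* **Log transform** uses base 2 by default so group coefficients read as
  doublings; the base is configurable because nothing downstream depends
  on it after pareto scaling.
* **Pareto scaling** maps each metabolite to (x − mean)/√sd with the n−1
  sd; columns with zero variance map to zeros.  After scaling, a column's
  variance equals its original standard deviation, which down-weights
  high-variance metabolites less aggressively than unit-variance scaling.

## Differential analysis

Per metabolite, OLS of the processed abundance on
[intercept, group (Fabry = 1), sex (M = 1), centred age] gives the group
coefficient ("logFC" on the processed scale — no back-transformation is
applied), residual variance s², and df = n − 4.  Variances are moderated by
empirical Bayes: the ensemble of log s² is moment-matched through
digamma/trigamma identities to an inverse-gamma prior (d₀, s₀²), giving

    s̃² = (d₀·s₀² + d·s²)/(d₀ + d),   t = β̂ / (s̃·√v),   t ~ t(d₀ + d)

with v the design-based variance factor of the group coefficient.  When
the empirical dispersion of the variances is at or below the chi-squared
theory, d₀ = ∞ and every s̃² collapses to the mean variance.  A test
cross-checks the whole moderation path against the reference R
implementation on a small fixture.

FDR control defaults to Benjamini–Yekutieli (step-up with the harmonic
c(m) factor), valid under the arbitrary dependence a metabolite panel
exhibits; plain Benjamini–Hochberg is available by config.  Significance
is adjusted p < α (α = 0.05); α ≥ 1 is treated as the everything-passes
boundary.

## Unsupervised stage

PCA is a column-centred SVD; explained-variance ratios span all components
and component signs are fixed (largest-magnitude loading positive).
Spearman screens correlate every metabolite with LysoGb3 and residual
enzyme activity on patients only (controls lack the biomarkers), with
midrank ties, t-approximation p-values and BH adjustment across the screen.
Hierarchical clustering is Ward on Euclidean distances by default — the
analysis fixes the distance, the linkage is a reporting choice.

## Network stage

Partial correlations come from the analytic variance-minimising shrinkage
of the sample correlation matrix toward the identity,
R* = (1 − λ)R + λI, pcorᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ) with Ω = (R*)⁻¹.  Shrinkage
guarantees invertibility at p = 188 > n ≤ 126.  One λ, estimated on the
full sample, is shared by every regime: pruning compares edge sets across
regimes of different sample size, and per-regime intensities would put
their partial correlations on incompatible scales (the n = 60 control
regime alone shrinks roughly three times harder than the combined one).

A network keeps edges by an absolute threshold |pcor| ≥ τ, τ = 0.15 by
default.  A top-q quantile rule is provided (and is the natural choice for
single-network analyses), but for this pipeline it is demonstrably
degenerate: it forces every regime to keep the same edge count, so
removing one patient merely swaps a fixed number of borderline noise edges
in and out, and the leave-one-out signatures become threshold churn with
an empty consensus.  τ sits deliberately near the strength that a genuine
disease edge retains after dilution by the control half of the combined
sample.

Pruning removes from a general network every edge present in a more
specific network, matched by unordered node pair (weights and signs
ignored).  When the control network is the pruning reference it is built
with a relaxed rule (τ → 0.5·τ), so control edges that the smaller control
sample detects weakly are still recognised as control physiology rather
than surviving as spurious "disease-specific" edges.  The disease-specific
network is prune(combined, control); each patient-specific signature is
the node set of prune(prune(controls + patients−i, control), disease).
Deduplicated non-empty signatures feed the consensus: metabolites present
in at least a fraction f of signatures (f = 0.3 by default; f = 1 is the
strict intersection).  The full frequency table is always emitted, and the
pipeline falls back to the most redundant metabolites if no metabolite
clears the cut, so the classifier always receives a candidate signature.

## Classification

Every non-empty subset of the consensus (2^k − 1, deterministic order) is
scored by repeated stratified cross-validation of a random forest
(defaults 500 trees, √p features, class-balanced bootstrap; 5 folds × 50
repeats).  Out-of-fold probabilities are pooled per repeat; the subset's
AUC is the mean of per-repeat pooled AUCs, the ROC curve and the 95%
percentile-bootstrap CI (2000 resamples) come from the per-sample mean
probability.  Per-subset seeds derive deterministically from the master
seed, so the leaderboard is reproducible and the evaluation is
embarrassingly parallel.  The leaderboard sorts by AUC, ties broken toward
smaller subsets.

## Synthetic cohort generator

The generator reproduces the study's design: 60 controls and 66 patients,
188 metabolites in p180 class proportions, log-normal concentrations
(baselines spanning ~0.05–200 µM, biological log-SDs 0.2–0.6), 86 planted
group shifts of 1.5 within-group SD with random signs, additive sex
(0.1 SD) and age (0.005 SD/year) effects with random per-metabolite signs,
ages uniform on the cohort's ranges (controls 18–56, patients 17–75,
sexes balanced), and 2% missingness (MCAR by default; a left-censored mode
drops low concentrations preferentially, as targeted panels do).

The control group follows a Gaussian graphical model with a modular,
nearly banded edge topology (chains of nearest/next-nearest neighbours in
blocks of ~10 plus sparse long-range pairs, density 0.03, |pcor| drawn in
[0.2, 0.5]).  Metabolite panels are strongly modular — neighbouring lipid
species correlate — and this topology keeps the precision matrix close to
positive definite, so the planted partial correlations survive the
diagonal-loading PD projection nearly unchanged.  A fully random graph at
the same density forces loading that roughly halves every planted value;
the truth object therefore always records *realized* partial correlations.

Patients share the control structure plus disease-only edges chaining the
13 disease-module metabolites with alternating strong (|pcor| 0.6–0.75)
and moderate (0.35–0.45) links, written onto the loaded control precision
so that targets are hit after minimal further loading.  Strong links model
tight disease-induced co-accumulation (substrate/product species); the
moderate tier sits near the detection boundary of the combined sample,
which is exactly where real disease edges diluted by controls live.  Each
patient's module deviations are scaled by a lognormal severity factor
(σ = 1.0), emulating the mild-to-severe clinical spectrum; this
heterogeneity is what makes leave-one-patient-out analysis informative —
with exchangeable patients, removing one sample perturbs nothing but
threshold noise.

Patient biomarkers are attached by a Gaussian copula on normal scores:
LysoGb3 log-normal and elevated, residual enzyme activity squashed into
low fractions, each with a configurable rank correlation to a chosen
planted metabolite.  Controls keep both missing.

What the generator does **not** emulate: batch effects, instrument drift,
calibration chemistry, left-censored detection limits (beyond the optional
mode), class-specific concentration distributions, or treatment effects on
metabolite levels.  Passing tests therefore demonstrate that the pipeline
recovers the structure it assumes, at these sample sizes — not that any
particular clinical cohort behaves this way.

## Numerical choices and degenerate inputs

Precision matrices are accepted when the smallest eigenvalue is ≥ 0.05
after loading; requesting infeasible structure raises with advice to lower
density or magnitudes.  Zero-variance metabolites pareto-scale to zeros.
Exact-zero residual variances are excluded from prior estimation and
shrink fully toward the prior.  Quantile edge selection breaks ties by the
lexicographically smaller node pair.  Trigamma inversion is Newton
iteration with the standard asymptotic fallbacks.  Leaf order in
dendrograms follows scipy's deterministic convention.  All randomness
flows from explicit integer seeds; derived seeds stay below 2³¹.

## Problem sizes for routine runs

The bundled analysis scripts and the acceptance script run the
classification stage at 3 folds × 5 repeats with 60 trees on the consensus
truncated to its 8 most redundant members (255 models), which profiles the
full 2^k enumeration behaviour at desk scale; the library defaults
(5 × 50, 500 trees, k ≤ 13 → 8191 models) are what a cluster run would
use.  Simulation-based checks use 10 seeds (recovery) and 20 seeds (null
behaviour).

## Known limitations

* The edge threshold τ is the single most result-sensitive choice; it is
  surfaced in every report and should be re-examined for panels or sample
  sizes different from 188 × 126.
* The strict consensus intersection is usually empty under realistic
  noise; the frequency-threshold consensus (f = 0.3) is the operative
  definition, and high-frequency borderline noise edges can enter it
  alongside disease-module metabolites.
* logFC values are on the processed (log-pareto) scale and are not
  back-transformable to concentration ratios.
* Covariate adjustment is additive only; no group × sex interaction, no
  phenotype-stratified analysis.
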