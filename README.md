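# fabrynet

Network-based analysis of plasma targeted-metabolomics profiles in Fabry
disease, an X-linked lysosomal storage disorder caused by α-galactosidase A
deficiency.  The package implements, as a tested and reusable pipeline, a
case/control analysis of a 188-metabolite Biocrates p180-style panel
measured in 60 healthy donors and 66 Fabry patients:

1. **Preprocessing** — nearest-neighbour (KNN) imputation of missing
   concentrations, log transform, pareto scaling ((x − mean)/√sd).
2. **Differential analysis** — per-metabolite linear models with sex and
   age as covariates, empirical-Bayes variance moderation
   (s̃² = (d₀s₀² + ds²)/(d₀ + d), t = β̂/(s̃√v) with t ∼ t(d₀+d)), and
   Benjamini–Yekutieli FDR control.
3. **Exploration** — centred-SVD PCA, Ward/Euclidean clustering, and
   Spearman screens of every metabolite against the disease biomarkers
   LysoGb3 and residual enzyme activity (patients only).
4. **Differential networks** — shrinkage partial-correlation matrices
   (R* = (1−λ)R + λI, pcorᵢⱼ = −Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ)) on three sample regimes;
   *pruning* (removing from a general network every edge present in a more
   specific one) yields the disease-specific network, and leave-one-patient-
   out pruning yields per-patient metabolic signatures whose recurrent
   metabolites form the **consensus signature**.
5. **Classification** — every non-empty subset of the consensus is scored
   by a random forest under repeated stratified cross-validation with
   ROC/AUC and a bootstrap CI.

Cohort data of this kind is rarely publicly deposited, so the package
ships a first-class synthetic cohort generator that reproduces the study
conditions (cohort sizes, panel composition, 86 planted 1.5-SD group
shifts, a 13-metabolite disease module with disease-only partial-correlation
edges, covariate effects, patient-severity heterogeneity, sporadic
missingness) together with the ground truth needed to score every stage.
See `docs/methods.md` for the model details and design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 0   # cohort + ground truth
python analysis/02_preprocess.py          # impute, log2, pareto
python analysis/03_differential.py        # moderated tests + BY FDR
python analysis/04_explore.py             # PCA, clustering, biomarkers
python analysis/05_network.py             # pruning + consensus signature
python analysis/06_classify.py            # exhaustive RF subsets
```

Output of the chain at seed 0:

```
cohort: 60 controls + 66 patients, 188 metabolites, 472 missing cells
imputed 472 cells; matrix now log-pareto
81 differential metabolites (composition {'glycerophospholipid': 41,
  'acylcarnitine': 16, 'biogenic_amine': 9, 'sphingomyelin': 8, 'amino_acid': 7})
sensitivity 0.94, observed FDR 0.000
PC1 explains 20.7% of the variance
recovered 92% of planted disease edges, 21% control contamination
29 disease-specific edges; 59 distinct patient signatures; consensus of 6
evaluated 63 models over 6 consensus metabolites
full model AUC 0.876 (CI 0.832-0.941)
```

Reading: of the 86 planted group shifts the moderated analysis recovers 94%
with no false positives surviving the conservative BY adjustment; the
disease-specific network finds 92% of the planted disease-only
partial-correlation edges; the leave-one-patient-out stage condenses 66
patients into 59 distinct signatures whose recurrent metabolites form a
6-metabolite consensus; and a random forest on the full consensus separates
patients from controls with AUC 0.876 — well above the median
single-metabolite model (0.539), the same qualitative pattern the
combination-beats-singles analysis is designed to expose.

The same pipeline runs end-to-end via the CLI
(`fabrynet run-all --seed 0 --out results/run`) or the library
(`fabrynet.run_all(RunConfig(...))`), and each stage accepts your own
CSV/TSV matrices instead of simulated ones (`fabrynet diff matrix.csv
metadata.csv annotation.csv`, ...).

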