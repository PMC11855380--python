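# multisub

Multiomics cancer subtyping by joint latent-variable modelling: a Python
library and CLI for discovering patient subgroups from stacked omics
profiles (e.g. DNA methylation, mRNA, miRNA), with survival-guided feature
selection and survival-based validation.

## Who this is for

Computational biologists who have per-patient omics matrices plus clinical
follow-up (survival time, event indicator) and want to ask: *do these
patients fall into molecular subgroups with distinct survival outcomes?*
The package also ships a synthetic-cohort generator with known latent
groups and group-linked survival, so every stage can be exercised and
validated without any external download.

## The method

1. **FSbyCox feature selection.** Each feature *x* of each omics block is
   standardized and fit one at a time with a univariate Cox proportional
   hazards model, h(t | x) = h₀(t)·exp(βx), by Newton–Raphson on the
   Breslow partial likelihood. Features with converged fits and two-sided
   p < 0.05 (normal approximation on β̂/se) are retained as
   survival-relevant.
2. **Stacking.** Selected blocks are per-feature z-scored and concatenated
   into one joint matrix X (patients × features), with block provenance
   retained.
3. **Gaussian-mixture clustering.** X is modelled as a k-component mixture
   of diagonal-covariance Gaussians fit by expectation–maximization
   (random or k-means++ initialization, best of several restarts). Two
   solvers are provided:
   - **EM** — the classical alternation of posterior computation (E-step)
     and weighted-moment updates (M-step) over all patients;
   - **EM\*** — a data-centric accelerator that pushes each patient into a
     per-cluster max-heap keyed by log density under their best-matching
     component, freezes ("settles") the best-explained top fraction of
     each heap, and re-runs E-steps only on the remaining active patients,
     with periodic re-scoring of settled patients and a final full pass.
     Both solvers count density evaluations, giving a hardware-independent
     cost comparison.
4. **Validation.** Hard subtype assignments (argmax posterior) are
   compared by the Kaplan–Meier product-limit estimator and the
   multi-group log-rank test; the chi-square p-value is the subtyping
   quality metric. Discovered subtypes can also be cross-tabulated against
   reference labels (e.g. PAM50) with an adjusted Rand index summary, and
   screened per subtype for differentially expressed features
   (|log2FC| ≥ 3.5 with Welch-test p < 0.05).

## Worked example

```python
from multisub import SynthConfig, generate, PipelineConfig, run_pipeline

cfg = SynthConfig(n_samples=300, k_true=3,
                  omics_specs=[("meth", 6, 14), ("mrna", 6, 14)],
                  separation=6.0, censor_rate=0.2, seed=2,
                  hazard_scales=[200.0, 800.0, 2500.0])
data = generate(cfg)
res = run_pipeline(data.omics, data.clinical, PipelineConfig(k=3), seed=5)
rep = res.report()
print(f"selected features per omics: {rep['n_selected']}")
print(f"cluster sizes: {rep['cluster_sizes']}")
print(f"log-rank: chi2 = {res.logrank.statistic:.1f}, "
      f"df = {res.logrank.df}, p = {res.logrank.p_value:.3g}")
print(f"density evaluations: {res.model.n_density_evals}")
```

prints

```
selected features per omics: {'meth': 6, 'mrna': 4}
cluster sizes: {1: 95, 2: 113, 3: 92}
log-rank: chi2 = 195.2, df = 2, p = 4.13e-43
density evaluations: 2598
```

Read: of 40 features in two omics blocks, 10 survive Cox screening; the
mixture splits the 300 patients into three groups of 95/113/92 whose
survival curves separate decisively (the three generated groups had mean
survival 200, 800 and 2500 days), at a cost of 2598 per-patient
per-component density evaluations. The recovered partition matches the
generating groups exactly (adjusted Rand index 1.0).

The same workflow is available from the shell:

```bash
multisub simulate --n 300 --k-true 3 --separation 6 --seed 2 --out data/
multisub run --omics meth=data/meth.tsv --omics mrna=data/mrna.tsv \
    --omics mirna=data/mirna.tsv --clinical data/clinical.tsv \
    --k 3 --seed 5 --out results/
multisub dropout ... ; multisub ksweep ... ; multisub cost ...
```

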