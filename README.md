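# cortexmeth

Trajectory modelling of DNA methylation across human prenatal cortex
development: per-site linear and Gaussian-process models of methylation
against developmental age, differentially methylated region calling,
co-methylation module detection, enrichment statistics and reference-based
cell-type deconvolution — exercised end-to-end on synthetic data with known
ground truth.

## Who this is for

Epigenomics researchers analysing array-based DNA methylation (beta values
in [0, 1]) measured across a developmental time course — here, bulk and
nuclei-sorted human cortex spanning 6–23 post-conception weeks (pcw) — who
want to (a) call developmentally differentially methylated positions (dDMPs)
and regions (dDMRs), (b) separate constant, linear and nonlinear
trajectories, (c) group nonlinear sites into co-methylation modules,
(d) test genomic-feature / open-chromatin / gene-set enrichment, and
(e) estimate cell composition from bulk profiles.

## The models at the core

**dDMPs.** For each site, OLS of the methylation proportion on age (pcw),
controlling for sex and batch; a site is a dDMP when the age coefficient's
two-sided p falls below the experiment-wide EPIC threshold, p < 9×10⁻⁸.
Effects are reported in percentage points per week.

**dDMRs.** Maximal chains of ≥3 dDMPs with consecutive gaps ≤500 bp, tested
with a correlation-adjusted inverse-variance meta-analysis: with
Σ = diag(s)·R·diag(s) (R the residual correlation of the member sites),
B = (1ᵀΣ⁻¹b)/(1ᵀΣ⁻¹1), SE = (1ᵀΣ⁻¹1)^(−1/2), z = B/SE; Bonferroni over
candidates.

**Trajectory classes.** Exact zero-mean GP regression under three nested
kernels sharing bias and noise terms — constant, constant + linear, and
constant + Matérn 5/2 — with hyperparameters chosen by multi-restart
maximisation of the log marginal likelihood. High-confidence nonlinear sites
need a log-likelihood ratio ≥2 against *both* simpler models and a
timescale (lengthscale) ≥10 pcw. A timescale ℓ corresponds to one full
oscillation every 2π√(3/5)·ℓ ≈ 5ℓ pcw.

**Modules.** Signed co-methylation adjacency ((1+cor)/2)¹², topological
overlap, average-linkage clustering with a static cut, eigengenes (first PC)
and hub sites (max kME).

**Deconvolution.** Reference probes are the top-100 |t| one-vs-rest
discriminators per cell type; bulk proportions come from non-negative least
squares, scored by the root-mean-square reconstruction error (CETYGO-style).

## Worked example

```python
import cortexmeth as cm

beta, sheet, truth = cm.simulate_dataset(n_sites=500, n_samples=91, seed=1)
res = cm.fit_site_linear(beta, sheet)
print(f"dDMPs (p < 9e-8): {int(res['dmp'].sum())} of {len(res)} sites")

top = res.loc[res["dmp"]].sort_values("log10_p").iloc[0]
print(f"top dDMP {top['site_id']}: {top['effect']:+.2f}% per week "
      f"(SE {top['se']:.3f}, p = {top['p']:.3g})")

filtered, report = cm.run_qc(beta)          # outlier masking + site filters
ages = sheet["age_value"].to_numpy()
pick = truth.groupby("true_class")["site_id"].head(4).tolist()
cls = cm.classify_sites(filtered.subset_sites(pick), ages, seed=1)
print("GP classes:", cls["class"].value_counts().to_dict())
print(f"timescale 1 -> period {cm.timescale_to_period(1.0):.2f} pcw")
```

prints

```
dDMPs (p < 9e-8): 172 of 500 sites
top dDMP site000328: +4.09% per week (SE 0.062, p = 2.84e-75)
GP classes: {'nonlinear': 5, 'constant': 4, 'linear': 3}
timescale 1 -> period 4.87 pcw
```

172 of 500 simulated sites change significantly with age (every linear site
plus the nonlinear sites whose net trend is strong); the top site gains
4.09% methylation per week, and the GP classifier separates the planted
constant/linear/nonlinear trajectories (one noisy linear site is called
nonlinear). A timescale of 1 corresponds to a full oscillation every ~5
weeks.

The same stages are scriptable from a shell:

```bash
cortexmeth simulate --seed 1 --out sim/
cortexmeth qc  --beta sim/beta.tsv --out qc/
cortexmeth dmp --beta qc/beta_qc.tsv --sheet sim/sample_sheet.tsv --out dmp/
cortexmeth gp  --beta qc/beta_qc.tsv --sheet sim/sample_sheet.tsv --seed 1 --out gp/
```

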