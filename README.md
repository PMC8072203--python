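# mrkit

Bidirectional two-sample Mendelian randomization (MR) for studies of blood
metabolites and binary disease outcomes, with the full sensitivity battery,
Bayesian model-averaged multivariable MR over correlated exposures, a
one-sample 2SLS replication path, and a ground-truth simulator so that every
stage is testable without access-controlled GWAS downloads.

## Who this is for

Genetic epidemiologists asking whether a modifiable biomarker (say, an NMR
lipoprotein subfraction or glycoprotein acetyls) causally influences a
disease such as Alzheimer's. Randomized alleles act as instrumental
variables: a SNP robustly associated with the exposure, independent of
confounders, and affecting the outcome only through the exposure identifies
the causal effect from two *separate* GWAS — one for the exposure, one for
the outcome.

## What it computes

With per-SNP summary statistics (β̂<sub>Xj</sub>, σ<sub>Xj</sub>) for the
exposure and (β̂<sub>Yj</sub>, σ<sub>Yj</sub>) for the outcome, harmonized
to a common effect allele:

- **IVW** — weighted regression of β̂<sub>Yj</sub> on β̂<sub>Xj</sub>
  through the origin, weights 1/σ<sub>Yj</sub>²; fixed-effect or
  multiplicative random-effects SE (floored at the fixed-effect SE).
- **MR-Egger** — the same regression with a free intercept; a non-null
  intercept is evidence of directional horizontal pleiotropy.
- **Weighted median** — the interpolated 50th weighted percentile of the
  per-SNP ratios β̂<sub>Yj</sub>/β̂<sub>Xj</sub>; consistent when ≥50% of
  the weight comes from valid instruments. Bootstrap SE.
- **Sensitivity battery** — Cochran's Q, leave-one-out, funnel tables, and
  MR-PRESSO (simulation-based global pleiotropy test, per-SNP outlier test,
  distortion test).
- **MR-BMA** — Bayesian model averaging over subsets S of K correlated
  exposures: β̂<sub>Yj</sub> = Σ<sub>k∈S</sub> θ<sub>k</sub>β̂<sub>Xjk</sub> + ε,
  θ ~ N(0, σ²I), subset prior p<sup>|S|</sup>(1−p)<sup>K−|S|</sup>
  (defaults p = 0.1, σ² = 0.25). Reports marginal inclusion probabilities
  (MIP), model-averaged causal effects (MACE), ranked model posteriors, and
  per-model Q / Cook's-distance influence diagnostics (flags at Q > 10,
  Cd > 4/J). Genetic-correlation pruning (rg > 0.95) removes
  indistinguishable exposures first.
- **One-sample 2SLS** — controls-only first stage of the (√-transformed,
  standardized) metabolite on risk-allele-oriented dosages, logistic second
  stage, weighted instrument-strength F.
- **Effective number of tests** — Li–Ji eigenvalue correction for
  correlated phenotype batteries, with the Nyholt variant as a flag.

## Worked example

`examples/01_forward_univariable_mr.py` simulates a two-sample study with a
true effect of 0.3 log-odds per SD (OR 1.35), selects instruments and runs
the estimators:

```
instruments surviving selection: 18 / 20
harmonized SNPs: 18  (actions: {'sign-flipped': 10, 'kept': 7, 'strand-flipped': 1})
ivw (multiplicative-re): beta=+0.284 (SE 0.029)  OR=1.33 [1.25, 1.41]  p=1.25e-22
                 egger: beta=+0.201 (SE 0.131)  OR=1.22 [0.95, 1.58]  p=1.45e-01
       weighted_median: beta=+0.274 (SE 0.039)  OR=1.32 [1.22, 1.42]  p=1.47e-12
Egger intercept: +0.0097 (p=0.52)
true causal effect: 0.3 log-odds per SD (OR 1.35)
```

All three estimators recover the planted OR within sampling error; the
Egger interval is wider (the price of relaxing the exclusion restriction)
and its intercept is compatible with zero, as expected with no simulated
pleiotropy. The other examples cover the outlier battery, MR-BMA with
rg pruning, one-sample 2SLS, and the orchestrated pipeline.

## Command line

```bash
mrpipe run  --config run.yaml   # forward and/or reverse univariable battery
mrpipe bma  --config run.yaml   # rg pruning + MR-BMA + diagnostics
mrpipe meff --corr corr.tsv     # effective tests and adjusted thresholds
```

The YAML config names the exposure/outcome summary-statistic files (tab
separated; configurable column dialect), filter settings (genome-wide
significance 5e-8, per-SNP F ≥ 10, MAF ≥ 0.01, region exclusions such as the
ApoE locus, LD clumping at r² ≤ 0.001 against a user-supplied LD table),
harmonization mode (forward-strand assumption, or dropping non-inferable
palindromic SNPs at MAF > 0.40), estimator settings and seeds. Outputs are
tab-separated report tables plus a JSON audit sidecar; every table carries
the config hash and seed, and reruns are byte-identical.

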