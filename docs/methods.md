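# Methods

## The inference problem

A metabolite measured in one GWAS (quantitative, per-SD units, ~25,000
samples) and a disease measured in another (case/control, log-odds units,
~64,000 samples with roughly a third cases) share no individuals. Genetic
variants robustly associated with the metabolite serve as instrumental
variables: under exchangeability (no association with confounders) and
exclusion restriction (no path to the disease except through the
metabolite), the ratio of a SNP's outcome effect to its exposure effect
estimates the causal effect. The package estimates that effect several ways,
stress-tests the assumptions, extends the model to many correlated
metabolites at once, and replicates in individual-level data.

## Instrument selection

Variants are retained when genome-wide significant for the exposure
(p < 5×10⁻⁸), strong (per-SNP F = (β/σ)² ≥ 10 — the summary-data
approximation to the regression F, used because source GWAS rarely publish
per-SNP R²), and common (MAF ≥ 0.01). Exposures with fewer than `min_snps`
(default 3) survivors are flagged excluded rather than estimated — a
two-instrument analysis has essentially no power and no sensitivity
analysis. Variants genome-wide significant for the *outcome* are excluded
(exchangeability risk), as are configured genomic regions: the ApoE locus
is pleiotropic for dementia-adjacent traits, and two interval presets ship
(`apoe-as-printed`: chr19:4.50–4.58 Mb; `apoe-grch37`: chr19:45.38–45.46 Mb,
the conventional GRCh37 coordinates). Which preset is right depends on the
coordinate convention of the input files, so it is a config choice, never a
guess. Region bounds are closed intervals on 1-based coordinates. LD
clumping is greedy on ascending p against a user-supplied r² table
(threshold 0.001); absent pairs are treated as independent with a warning.
No reference-panel queries — the package is download-free by design.

All row-wise filters are idempotent and order-free; the audit sidecar
records counts removed per filter, and `instruments_in = instruments_used +
Σ exclusions` reconciles exactly.

## Harmonization

Effect alleles are aligned SNP-by-SNP: identical pairs kept, swapped pairs
sign-flipped (frequency complemented), complementary-strand pairs
base-complemented first. Palindromic SNPs (A/T, C/G) cannot be resolved
from alleles: the default `assume-forward` mode matches alleles literally
(both GWAS assumed forward-strand coded); the `drop-noninferable`
sensitivity mode drops them when MAF > 0.40 on either side and otherwise
orients by frequency-side agreement. When the outcome GWAS reports no
allele frequencies, the exposure frequency stands in. Matching is by SNP id
(rsID-keyed catalogs); duplicated ids resolve to the smallest exposure p
with a logged count. Multivariable harmonization takes the union of
per-exposure instruments, requires every exposure to report each retained
SNP (directly or via a user-supplied proxy map), and errors when fewer than
K+2 SNPs survive — below that the K-exposure model is unidentifiable.

## Estimators

First-order weights w<sub>j</sub> = 1/σ<sub>Yj</sub>² (exposure-side
uncertainty ignored) throughout, matching standard two-sample practice.

**IVW.** β̂ = Σw<sub>j</sub>β<sub>Xj</sub>β<sub>Yj</sub> / Σw<sub>j</sub>β<sub>Xj</sub>².
The default SE is multiplicative random-effects — the fixed-effect SE times
max(1, √(Q/(J−1))) — so heterogeneity widens intervals but underdispersion
never narrows them; the fixed-effect variant is a flag. Two-sided normal
p-values.

**MR-Egger.** Weighted regression with a free intercept after orienting all
instruments to β<sub>Xj</sub> ≥ 0 (the estimator is not invariant to joint
sign flips without this convention). The intercept estimates the average
directional pleiotropic effect; both SEs carry a residual scale factor
floored at 1; p-values use t(J−2) for small-J robustness. Egger's slope is
attenuated when instrument effects carry non-negligible estimation error
(I²<sub>GX</sub> < 1); the recovery simulations therefore run in a
large-exposure-GWAS regime where the estimator is consistent.

**Weighted median.** Ratios r<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub>
with weights β<sub>Xj</sub>²/σ<sub>Yj</sub>², sorted; cumulative weights at
interval midpoints; linear interpolation at 0.5. SE from a parametric
bootstrap (resampling both β<sub>X</sub> and β<sub>Y</sub> from their
sampling distributions), 5,000 replicates by default, seed mandatory.

**Sensitivity.** Cochran's Q = Σw'<sub>j</sub>(r<sub>j</sub> − β̂)² with the
median's weights, df = J−1. Leave-one-out recomputes IVW J times and flags
SNPs whose removal moves p across 0.05 or flips the sign. Funnel tables
(ratio vs precision) are emitted plot-ready; no rendering.

**MR-PRESSO.** Observed RSS uses leave-one-out predictive slopes; its null
distribution comes from `n_sim` (default 1,000) parametric re-simulations
under the fitted model, with add-one smoothing so p ≥ 1/(n_sim+1). Per-SNP
outlier tests compare each observed residual with its simulated
distribution at Bonferroni α/J; outlier and distortion tests run only when
the global p < 0.05. The corrected estimate is exactly fixed-effect IVW on
the non-outlier subset; the distortion null resamples random same-size SNP
subsets. Fully reproducible given the seed.

## MR-BMA

Rows are scaled by 1/σ<sub>Yj</sub> (unit outcome variance) and each
exposure column standardized to unit weighted norm so one prior variance is
comparable across exposures. For a subset S, the marginal likelihood of
y = X<sub>S</sub>θ + ε, θ ~ N(0, σ²I), ε ~ N(0, I) is closed-form (computed
via Woodbury identities; only an |S|×|S| solve). Defaults follow the
convention for this analysis family: inclusion prior 0.1, σ² = 0.25, and a
stochastic-search budget z = 10,000. With K ≤ 16 the implementation
enumerates all 2<sup>K</sup> subsets instead — the exact posterior at K = 9
costs 512 closed-form fits and removes Monte-Carlo error; the seeded
shotgun search (add/delete/swap proposals, Metropolis acceptance,
normalization over visited models) serves K > 16 and replication of the
stochastic mode. MIP<sub>k</sub> sums posterior probability over models
containing k; MACE<sub>k</sub> averages the *ridge posterior-mean*
conditional effect (not the OLS fit — consistent with the Bayesian model
average), mapped back to log-odds per SD, with zeros when excluded — hence
its deliberate shrinkage toward the null. Per-model diagnostics use the
plain weighted least-squares fit: q<sub>j</sub> is the squared standardized
residual and Cd<sub>j</sub> the leverage-form Cook's distance (identical to
delete-one refitting); flags at q > 10 and Cd > 4/J (0.19 at J = 21).

Exposure pruning: while any |rg| > 0.95 remains, drop the lower-priority
member of the most correlated pair (priority: e.g. univariable |z|; ties
break lexicographically). Near-duplicate exposures are statistically
indistinguishable in the regression and would split inclusion probability
arbitrarily.

## One-sample 2SLS

Metabolite preprocessing is √-transform then standardize (that order is a
package convention; the reverse is one flag away and the report records
which ran). Instruments are flipped to exposure-increasing alleles
(dose → 2−dose). The first stage is least squares on the controls only —
cases' metabolite levels may already reflect disease, so a mixed first
stage risks reverse-causation bias — and predictions extend to all samples.
The second stage is logistic (the outcome is a diagnosis and the estimand
an OR); a linear-probability option exists for diagnostics. The reported SE
ignores first-stage estimation error and says so in the result. "Weighted
by instrument strength" is realized as per-IV variance-explained weights;
for the joint least-squares first stage column weights cannot change the
predictions (they rescale coefficients exactly), so their real effect is in
the combined F = Σv<sub>j</sub>F<sub>j</sub>/Σv<sub>j</sub>, with F < 10
flagging weak instruments.

## Multiple testing

Correlated metabolites are fewer than K independent tests. The Li–Ji
eigenvalue count Σ[1(λ≥1) + (λ−⌊λ⌋)] is the default (eigenvalues snapped to
integers within 1e-9 so exact block structures count exactly); Nyholt's
1+(K−1)(1−var(λ)/K) is a flag. The adjusted threshold is α/M<sub>eff</sub>,
reported at two significant figures beside full precision.

## The simulator

`synth` generates the study conditions, not a convenience fixture. Defaults
mirror the motivating geometry: J = 21 shared instruments, K = 9 correlated
exposures, a 25,000-sample quantitative exposure GWAS, and a 63,926-sample
case/control outcome GWAS with case fraction 0.344 — the outcome SE uses
the binary-trait form 1/√(2·maf(1−maf)·n·cf(1−cf)), which makes simulated
per-SNP outcome z-scores match what disease GWAS of that size actually
show (a case/control study is ~2× noisier than a quantitative one of equal
n). True instrument effects have magnitudes uniform on 0.06–0.15 SD
(strong enough to reach genome-wide significance at n = 25,000, as real
published instruments are), coupled across exposures through a Gaussian
copula on the configured correlation matrix; signs are random unless
`positive_effects` codes every instrument by its exposure-increasing allele
— the convention under which directional pleiotropy is meaningful, since
orientation otherwise re-balances it. Pleiotropy assigns a configurable
fraction of SNPs direct outcome effects (mean-zero when balanced).
Allele metadata are emitted with configurable fractions swapped and
strand-complemented so harmonization is exercised end-to-end; palindromic
SNPs are never strand-flipped (indistinguishable from a swap, hence
unrecoverable by construction). Cohorts draw Hardy–Weinberg dosages, build
the exposure linearly, and tune the logistic intercept to the target case
fraction by root finding. Genetic-correlation matrices are normalized Gram
matrices of block factor loadings — positive semidefinite by construction.

What the simulator does not emulate: LD between instruments (post-clumping
independence is assumed, as in curated instrument catalogs), liability-scale
effects (outcome effects are drawn directly on the log-odds scale that the
estimators consume), sample overlap between the two GWAS, population
stratification, and genotype missingness/imputation error. Passing tests
therefore certify the estimators' behavior under the stated sampling model,
not robustness to those additional real-data pathologies.

## Problem sizes and regimes in the checks

Calibration checks (IVW type-I error, the null Q distribution, 2SLS null
rejection) run at the study-scale sample sizes; the type-I check uses the
fixed-effect IVW variant, which is the correctly specified one under the
no-pleiotropy null (the random-effects default is conservative by
construction, measured ≈0.03–0.04). Recovery checks (coverage, Egger
intercept recovery, BMA ranking) run at larger GWAS sizes
(10⁵–2.5×10⁵), where the estimators' consistency conditions hold; at the
study scale the nine-exposure ranking problem with within-block rg = 0.9 is
genuinely hard (top-rank rate ≈0.7), consistent with the modest inclusion
probabilities such analyses report on real data. Repetition counts: 2,000
null replicates, 500 coverage/bias replicates, 100 ranking replicates, 20
outlier-detection runs; bootstrap sizes inside repetition loops are 100–500
(the SE of a bootstrap SE is immaterial to coverage at that scale), 5,000
for single analyses.

## Known limitations

- No LD-proxy discovery, liftover, or remote catalog access; all inputs are
  local files.
- Egger and weighted-median SEs are first-order/bootstrap conveniences, not
  exact small-sample intervals.
- The 2SLS SE is not corrected for first-stage uncertainty (flagged in the
  output); with weak instruments the interval is optimistic.
- MACE is shrunk toward zero by design and should be read for direction and
  relative magnitude, not as an unbiased effect size.
- σ² in MR-BMA is fixed, not cross-validated; when the standardized signal
  is far outside the prior scale, spurious co-inclusion of correlated
  exposures can occur (visible in simulations at implausibly large outcome
  GWAS sizes).
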