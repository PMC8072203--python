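"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a two-sample MR study of blood
metabolites on a binary disease outcome:

* two non-overlapping GWAS samples — a metabolite GWAS of ~25,000
  individuals and a disease GWAS of ~63,900 (the default sample sizes) —
  each reporting per-SNP effect, SE, p and allele metadata;
* K correlated exposures instrumented by a shared pool of J independent
  SNPs (independence stands in for post-clumping instruments);
* a binary outcome generated on the log-odds scale: each SNP's true outcome
  effect is the causal combination of its exposure effects plus an optional
  pleiotropic direct effect (balanced or directional);
* per-SNP sampling noise with the standard SE approximation
  ``1 / sqrt(2 maf (1-maf) n)``;
* allele bookkeeping: a configurable fraction of outcome rows is emitted
  with swapped or strand-complemented alleles so harmonization is exercised;
* an individual-level cohort with Hardy-Weinberg dosages at the same kind of
  instruments, for the one-sample 2SLS stage;
* block-structured genetic-correlation matrices emulating tightly clustered
  lipoprotein subfractions.

Everything is driven by a mandatory seed; identical configs give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .gwas_io import VariantAssociation
from .mrbma import RgMatrix
from .osmr import CohortData

__all__ = [
    "SimConfig",
    "simulate_two_sample",
    "simulate_cohort",
    "simulate_rg",
    "to_harmonized",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("A", "T"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the two-sample summary-statistic simulator.

    Defaults mirror the geometry of the motivating study: 21 shared
    instruments, 9 correlated metabolite exposures, a ~25k-sample exposure
    GWAS and a ~63.9k-sample outcome GWAS, instrument effects strong enough
    to pass genome-wide significance at those sample sizes.
    """

    J: int = 21
    K: int = 9
    n_exposure: int = 25000
    n_outcome: int = 63926
    theta: np.ndarray | list[float] | float = 0.0
    exposure_corr: np.ndarray | None = None
    #: (fraction_invalid, mean_alpha, sd_alpha, balanced)
    pleiotropy: tuple[float, float, float, bool] = (0.0, 0.0, 0.0, True)
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: magnitude range of true per-SNP effects on the exposures (SD units)
    effect_range: tuple[float, float] = (0.06, 0.15)
    #: code every instrument by its exposure-increasing allele (true effects
    #: all positive) — the convention under which directional pleiotropy is
    #: directional relative to the fitted orientation
    positive_effects: bool = False
    #: fraction of outcome rows emitted allele-swapped / strand-flipped
    frac_swapped: float = 0.0
    frac_strand_flipped: float = 0.0
    #: case fraction of the (binary) outcome GWAS; log-odds SEs scale with
    #: 1/sqrt(n * cf * (1-cf)), so a case-control study of n samples is far
    #: noisier than a quantitative GWAS of the same n
    outcome_case_fraction: float = 0.344
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        theta = np.atleast_1d(np.asarray(self.theta, float))
        if theta.size == 1 and self.K > 1:
            theta = np.repeat(theta, self.K)
        if theta.size != self.K:
            raise ValueError(f"theta has {theta.size} entries for K={self.K}")
        self.theta = theta
        if self.exposure_corr is None:
            self.exposure_corr = np.eye(self.K)
        self.exposure_corr = np.asarray(self.exposure_corr, float)
        if self.exposure_corr.shape != (self.K, self.K):
            raise ValueError("exposure_corr shape does not match K")
        frac = self.pleiotropy[0]
        if not 0 <= frac <= 1:
            raise ValueError("pleiotropy fraction must be in [0, 1]")


def _gwas_se(maf: np.ndarray, n: int, case_fraction: float | None = None) -> np.ndarray:
    """Standard per-SNP SE approximation.

    Quantitative trait (per-SD units): ``1/sqrt(2 maf (1-maf) n)``. Binary
    trait (log-odds units): the same with ``n`` replaced by the effective
    ``n * cf * (1-cf)`` of the case/control split.
    """
    eff_n = n if case_fraction is None else n * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * eff_n)


def _records(
    snp_ids: list[str],
    ea: list[str],
    oa: list[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[VariantAssociation]:
    from scipy import stats

    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return [
        VariantAssociation(
            snp_id=snp_ids[j],
            chrom=str(1 + j % 22),
            pos=1_000_000 * (1 + j),
            effect_allele=ea[j],
            other_allele=oa[j],
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pvalue=max(float(p[j]), 5e-324),
            n=n,
        )
        for j in range(len(snp_ids))
    ]


def simulate_two_sample(config: SimConfig) -> tuple[dict[str, list[VariantAssociation]], list[VariantAssociation], dict]:
    """Simulate two-sample GWAS summary statistics with known ground truth.

    Returns ``(exposure_tables, outcome_table, truth)`` where
    ``exposure_tables`` maps exposure id to a list of records, and ``truth``
    stores the true causal effects, true per-SNP effects, pleiotropy draws
    and allele bookkeeping needed by recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    j, k = config.J, config.K
    maf = rng.uniform(*config.maf_range, size=j)
    snp_ids = [f"rs{1000 + i}" for i in range(j)]
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=j)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    # true per-SNP exposure effects: magnitudes drawn in effect_range
    # (instrument-strength realism), correlated across exposures through a
    # Gaussian copula on the latent exposure correlation; one sign per SNP,
    # shared across exposures
    from scipy import stats as _stats

    chol = np.linalg.cholesky(config.exposure_corr + 1e-12 * np.eye(k))
    z = rng.normal(size=(j, k)) @ chol.T
    u = _stats.norm.cdf(z)
    lo, hi = config.effect_range
    if config.positive_effects:
        bx_true = lo + (hi - lo) * u
    else:
        # inverse CDF of the symmetric two-sided uniform on +-[lo, hi]: the
        # copula then carries both sign and magnitude dependence, so
        # exposure_corr = I yields independent effects (and signs)
        bx_true = np.where(
            u < 0.5,
            -hi + (hi - lo) * 2.0 * u,
            lo + (hi - lo) * (2.0 * u - 1.0),
        )

    frac_invalid, mean_alpha, sd_alpha, balanced = config.pleiotropy
    n_invalid = int(round(frac_invalid * j))
    invalid = np.zeros(j, bool)
    if n_invalid:
        invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if n_invalid:
        mu = 0.0 if balanced else mean_alpha
        alpha[invalid] = rng.normal(mu, sd_alpha, size=n_invalid)

    by_true = bx_true @ config.theta + alpha

    se_x = _gwas_se(maf, config.n_exposure)
    se_y = _gwas_se(maf, config.n_outcome, config.outcome_case_fraction)
    bx_obs = bx_true + rng.normal(size=(j, k)) * se_x[:, None]
    by_obs = by_true + rng.normal(size=j) * se_y

    exposures: dict[str, list[VariantAssociation]] = {}
    for c in range(k):
        exposures[f"exposure_{c}"] = _records(
            snp_ids, ea, oa, maf, bx_obs[:, c], se_x, config.n_exposure
        )

    # emit some outcome rows reoriented, to exercise harmonization
    out_ea, out_oa = list(ea), list(oa)
    out_beta = by_obs.copy()
    out_eaf = maf.copy()
    u = rng.random(j)
    swapped = u < config.frac_swapped
    flipped = (u >= config.frac_swapped) & (
        u < config.frac_swapped + config.frac_strand_flipped
    )
    for idx in np.flatnonzero(swapped):
        out_ea[idx], out_oa[idx] = out_oa[idx], out_ea[idx]
        out_beta[idx] = -out_beta[idx]
        out_eaf[idx] = 1.0 - out_eaf[idx]
    for idx in np.flatnonzero(flipped):
        # a strand flip of a palindromic SNP is indistinguishable from an
        # allele swap, so only non-palindromic SNPs are emitted flipped
        if _COMPLEMENT[out_ea[idx]] == out_oa[idx]:
            flipped[idx] = False
            continue
        out_ea[idx] = _COMPLEMENT[out_ea[idx]]
        out_oa[idx] = _COMPLEMENT[out_oa[idx]]
    outcome = _records(snp_ids, out_ea, out_oa, out_eaf, out_beta, se_y, config.n_outcome)

    truth = {
        "theta": np.asarray(config.theta).copy(),
        "bx_true": bx_true,
        "by_true": by_true,
        "alpha": alpha,
        "invalid": invalid,
        "maf": maf,
        "snp_ids": snp_ids,
        "swapped": swapped,
        "strand_flipped": flipped,
    }
    return exposures, outcome, truth


def to_harmonized(
    exposures: dict[str, list[VariantAssociation]],
    outcome: list[VariantAssociation],
) -> "HarmonizedDataset":
    """Assemble simulated tables directly into a HarmonizedDataset.

    Assumes the simulator emitted aligned alleles (``frac_swapped`` and
    ``frac_strand_flipped`` both zero); use :func:`mrkit.harmonize` paths
    when they are not. Skipping harmonization keeps repeated-simulation
    loops (calibration, coverage) fast.
    """
    from .harmonize import HarmonizedDataset

    exposure_ids = list(exposures)
    first = exposures[exposure_ids[0]]
    snp_ids = [v.snp_id for v in first]
    bx = np.column_stack([[v.beta for v in exposures[e]] for e in exposure_ids])
    sx = np.column_stack([[v.se for v in exposures[e]] for e in exposure_ids])
    out_by_id = {v.snp_id: v for v in outcome}
    by = np.array([out_by_id[s].beta for s in snp_ids])
    sy = np.array([out_by_id[s].se for s in snp_ids])
    return HarmonizedDataset(
        snp_ids=snp_ids,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        exposure_ids=exposure_ids,
    )


def simulate_cohort(
    n: int,
    J: int,
    per_iv_effects: np.ndarray | list[float],
    theta: float,
    case_fraction: float = 0.5,
    maf_range: tuple[float, float] = (0.1, 0.5),
    exposure_noise_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[CohortData, dict]:
    """Simulate an individual-level case/control cohort for one-sample MR.

    Dosages are Hardy-Weinberg binomial(2, maf); the exposure is the linear
    dosage combination plus normal noise; case status follows a logistic
    model with log-odds ``theta`` per exposure unit, the intercept tuned so
    the expected case fraction matches ``case_fraction``.
    """
    if seed is None:
        raise ValueError("simulate_cohort requires a seed")
    effects = np.asarray(per_iv_effects, float)
    if effects.size != J:
        raise ValueError(f"per_iv_effects has {effects.size} entries for J={J}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=J)
    dosages = rng.binomial(2, maf, size=(n, J)).astype(float)
    exposure = dosages @ effects + rng.normal(0, exposure_noise_sd, size=n)

    lin = theta * exposure

    def mean_case(intercept: float) -> float:
        return float(special.expit(intercept + lin).mean()) - case_fraction

    intercept = optimize.brentq(mean_case, -30, 30)
    outcome = (rng.random(n) < special.expit(intercept + lin)).astype(int)
    cohort = CohortData(
        sample_ids=[f"s{i}" for i in range(n)],
        dosages=dosages,
        exposure=exposure,
        outcome=outcome,
        snp_ids=[f"rs{2000 + i}" for i in range(J)],
    )
    truth = {"theta": theta, "intercept": intercept, "maf": maf, "effects": effects}
    return cohort, truth


def simulate_rg(
    K: int,
    blocks: int,
    within_block_rg: float = 0.9,
    noise: float = 0.0,
    seed: int | None = None,
) -> RgMatrix:
    """Block-structured genetic-correlation matrix, PSD by construction.

    Exposures are assigned round-robin to ``blocks`` latent factors with
    loading ``sqrt(within_block_rg)``; optional extra loadings of scale
    ``noise`` on a shared random factor perturb the block structure. The
    matrix is a normalized Gram matrix, hence positive semidefinite.
    """
    if seed is None:
        raise ValueError("simulate_rg requires a seed")
    if not 0 <= within_block_rg <= 1:
        raise ValueError("within_block_rg must be in [0, 1]")
    rng = np.random.default_rng(seed)
    load = np.zeros((K, blocks + 1))
    for i in range(K):
        load[i, i % blocks] = math.sqrt(within_block_rg)
    if noise > 0:
        load[:, blocks] = rng.normal(0, noise, size=K)
    # unit diagonal: residual variance tops up each row
    m = load @ load.T
    # top up each row's residual variance to reach a unit diagonal; rows whose
    # loadings already exceed unit variance are handled by the normalization
    resid = np.clip(1.0 - np.diag(m), 0.0, None)
    m = m + np.diag(resid)
    d = np.sqrt(np.diag(m))
    rg = m / np.outer(d, d)
    return RgMatrix(
        exposure_ids=[f"exposure_{i}" for i in range(K)],
        rg=rg,
    )
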