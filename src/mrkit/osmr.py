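"""One-sample Mendelian randomization by two-stage least squares.

Individual-level replication on a case/control cohort: per-sample genotype
dosages at the instrument SNPs, a metabolite level, and a binary diagnosis.

Stage 1 regresses the (square-root-transformed, standardized) metabolite on
all instrument dosages. To avoid bias from selection and reverse causation —
cases' metabolite levels may already reflect disease — the first stage is fit
on controls only by default, then used to predict the genetically
instrumented exposure for everyone. Stage 2 is a logistic regression of
case/control status on that prediction, reported as an odds ratio per 1 SD
of exposure. The stage-2 standard error is not corrected for first-stage
uncertainty; the result carries that flag.

Instrument strength is summarized by a weighted F-statistic: per-IV F from
simple regressions on the first-stage subset, combined with
variance-explained weights. F < 10 flags weak-instrument bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .uvmr import MREstimate, Z95

__all__ = [
    "CohortData",
    "preprocess_metabolite",
    "orient_risk_alleles",
    "two_stage",
    "weighted_f",
    "read_cohort",
]


@dataclass(slots=True)
class CohortData:
    """Individual-level dosages, exposure and binary outcome for one-sample MR."""

    sample_ids: list[str]
    dosages: np.ndarray  # N x J, effect-allele dose in [0, 2]
    exposure: np.ndarray  # N, metabolite level
    outcome: np.ndarray  # N, 1 = case
    snp_ids: list[str] = field(default_factory=list)
    iv_weights: np.ndarray | None = None  # J, per-IV instrument strength

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        self.exposure = np.asarray(self.exposure, float)
        self.outcome = np.asarray(self.outcome)
        n = len(self.sample_ids)
        if self.dosages.shape[0] != n or len(self.exposure) != n or len(self.outcome) != n:
            raise ValueError("cohort arrays have inconsistent sample dimension")
        if np.isnan(self.dosages).any() or np.isnan(self.exposure).any():
            raise ValueError("cohort contains missing cells; preprocess first")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if not self.snp_ids:
            self.snp_ids = [f"iv{j}" for j in range(self.dosages.shape[1])]

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.outcome) - self.outcome.sum())


def preprocess_metabolite(values: np.ndarray) -> np.ndarray:
    """Square-root transform, then standardize to mean 0 and SD 1.

    The root transform pulls in the right skew typical of metabolite
    concentrations; standardization puts every metabolite on the same
    per-SD scale used by the summary-data analyses.
    """
    values = np.asarray(values, float)
    neg = np.flatnonzero(values < 0)
    if neg.size:
        raise ValueError(
            f"negative value(s) at sample index(es) {neg.tolist()}; "
            "square-root transform undefined"
        )
    t = np.sqrt(values)
    sd = t.std(ddof=0)
    if sd == 0:
        raise ValueError("metabolite vector is constant; cannot standardize")
    return (t - t.mean()) / sd


def orient_risk_alleles(
    dosages: np.ndarray, per_iv_betas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flip IVs so each counts the exposure-increasing allele.

    For each instrument with a negative exposure effect: dose -> 2 - dose and
    beta -> -beta. Idempotent once all betas are non-negative.
    """
    dosages = np.asarray(dosages, float)
    betas = np.asarray(per_iv_betas, float)
    flip = betas < 0
    out_d = dosages.copy()
    out_d[:, flip] = 2.0 - out_d[:, flip]
    out_b = np.where(flip, -betas, betas)
    return out_d, out_b


def _per_iv_strength(
    dosages: np.ndarray, exposure: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-IV F statistic and variance explained from simple regressions."""
    n, j = dosages.shape
    f = np.empty(j)
    r2 = np.empty(j)
    for k in range(j):
        x = dosages[:, k]
        vx = x.var(ddof=0)
        if vx == 0:
            f[k] = 0.0
            r2[k] = 0.0
            continue
        r = np.corrcoef(x, exposure)[0, 1] ** 2
        r2[k] = r
        f[k] = (n - 2) * r / (1 - r) if r < 1 else float("inf")
    return f, r2


def weighted_f(cohort: CohortData, first_stage_subset: str = "controls-only") -> float:
    """Combined instrument-strength F, weighted by per-IV variance explained.

    ``F = sum(v_j F_j) / sum(v_j)`` with v_j the variance in the exposure
    explained by IV j on the first-stage subset. Values below 10 are the
    conventional weak-instrument flag.
    """
    mask = _stage1_mask(cohort, first_stage_subset)
    f, v = _per_iv_strength(cohort.dosages[mask], cohort.exposure[mask])
    if v.sum() == 0:
        return 0.0
    return float(np.sum(v * f) / v.sum())


def _stage1_mask(cohort: CohortData, first_stage_subset: str) -> np.ndarray:
    if first_stage_subset == "controls-only":
        return np.asarray(cohort.outcome == 0)
    if first_stage_subset == "all":
        return np.ones(len(cohort.sample_ids), bool)
    raise ValueError(f"unknown first_stage_subset {first_stage_subset!r}")


def two_stage(
    cohort: CohortData,
    first_stage_subset: str = "controls-only",
    stage2: str = "logistic",
) -> MREstimate:
    """Two-stage least squares with a binary outcome.

    Stage 1: least-squares fit of the exposure on all oriented dosages over
    the chosen subset (default controls only), IV columns scaled by
    ``iv_weights`` when provided — note the joint fit's predictions are
    invariant to column scaling, so the weights matter for bookkeeping and
    the combined F, not the prediction. Stage 2: logistic regression of the
    outcome on the stage-1 prediction for all samples; the coefficient is a
    log-odds ratio per 1 SD of exposure. ``stage2='linear'`` fits a
    linear-probability model instead (diagnostic use).

    The reported SE ignores first-stage estimation error (flagged in
    ``extra['se_uncorrected_for_stage1']``).
    """
    mask = _stage1_mask(cohort, first_stage_subset)
    design = cohort.dosages
    if cohort.iv_weights is not None:
        design = design * np.asarray(cohort.iv_weights, float)[None, :]
    x1 = sm.add_constant(design[mask], has_constant="add")
    rank = np.linalg.matrix_rank(x1)
    if rank < x1.shape[1]:
        raise ValueError(
            "stage-1 design is singular; collinear instruments among "
            f"{cohort.snp_ids}"
        )
    stage1 = sm.OLS(cohort.exposure[mask], x1).fit()
    pred = sm.add_constant(design, has_constant="add") @ stage1.params

    y = np.asarray(cohort.outcome, float)
    x2 = sm.add_constant(pred, has_constant="add")
    if stage2 == "logistic":
        fit = sm.Logit(y, x2).fit(disp=0)
    elif stage2 == "linear":
        fit = sm.OLS(y, x2).fit()
    else:
        raise ValueError(f"unknown stage2 {stage2!r}")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return MREstimate(
        method=f"2sls ({stage2}, {first_stage_subset})",
        beta=beta,
        se=se,
        n_snp=cohort.dosages.shape[1],
        extra={
            "n_cases": cohort.n_cases,
            "n_controls": cohort.n_controls,
            "weighted_f": weighted_f(cohort, first_stage_subset),
            "se_uncorrected_for_stage1": True,
        },
    )


def read_cohort(dosage_path: str, phenotype_path: str) -> CohortData:
    """Assemble a cohort from a dosage table and a phenotype table.

    The dosage table is samples x SNPs with a ``sample_id`` column, or the
    variant-major transpose (first column named ``SNP``), auto-detected from
    the header. The phenotype table has columns sample_id, exposure, outcome.
    Samples are matched by id; rows missing from either table are dropped.
    """
    dos = pd.read_csv(dosage_path, sep="\t")
    if dos.columns[0].lower() in ("snp", "snp_id", "variant"):
        dos = dos.set_index(dos.columns[0]).T.reset_index(names="sample_id")
    elif dos.columns[0].lower() != "sample_id":
        dos = dos.rename(columns={dos.columns[0]: "sample_id"})
    phe = pd.read_csv(phenotype_path, sep="\t")
    merged = phe.merge(dos, on="sample_id", how="inner").dropna()
    snp_cols = [c for c in dos.columns if c != "sample_id"]
    return CohortData(
        sample_ids=[str(s) for s in merged["sample_id"]],
        dosages=merged[snp_cols].to_numpy(float),
        exposure=merged["exposure"].to_numpy(float),
        outcome=merged["outcome"].to_numpy(int),
        snp_ids=list(snp_cols),
    )
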