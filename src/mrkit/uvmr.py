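"""Univariable two-sample Mendelian randomization estimators.

All estimators consume a :class:`~mrkit.harmonize.HarmonizedDataset` with a
single exposure column: per-SNP exposure effects ``bx`` with errors ``sx``
and outcome effects ``by`` with errors ``sy``, instruments assumed
independent (post-clumping). Weights are first-order, conditioning only on
the outcome variance.

* ``ivw`` — inverse-variance-weighted estimate: the weighted regression of
  ``by`` on ``bx`` through the origin, expressing the exclusion-restriction
  assumption that instruments act on the outcome only through the exposure.
* ``egger`` — the same regression with a free intercept; a non-null
  intercept is evidence of directional horizontal pleiotropy.
* ``weighted_median`` — the 50th weighted percentile of the per-SNP ratio
  estimates; consistent when at least half the weight comes from valid
  instruments.
* ``cochran_q``, ``leave_one_out``, ``funnel_data`` — the heterogeneity and
  influence battery.

For a binary outcome the causal effect is on the log-odds scale per 1 SD of
exposure; ``to_odds_ratio`` exponentiates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats

from .harmonize import HarmonizedDataset

Z95 = float(stats.norm.ppf(0.975))


@dataclass(slots=True)
class MREstimate:
    """A causal estimate with uncertainty, heterogeneity and method metadata."""

    method: str
    beta: float
    se: float
    n_snp: int
    pvalue: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    q: float = float("nan")
    q_df: int = 0
    q_p: float = float("nan")
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se
        if math.isnan(self.pvalue):
            if self.se > 0:
                self.pvalue = 2 * float(stats.norm.sf(abs(self.beta) / self.se))
            else:
                self.pvalue = 0.0 if self.beta != 0 else 1.0

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "n_snp": self.n_snp,
            "q": self.q,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
        }


def _univariable(data: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if data.n_exposures != 1:
        raise ValueError("univariable estimator requires a single-exposure dataset")
    return data.univariable(0)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MREstimate:
    """Single-instrument ratio estimate ``by/bx`` with first-order SE ``sy/|bx|``."""
    if bx == 0:
        raise ValueError("wald ratio undefined for bx = 0")
    return MREstimate(method="wald_ratio", beta=by / bx, se=sy / abs(bx), n_snp=1)


def _ratio_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and their first-order inverse-variance weights."""
    if np.any(bx == 0):
        raise ValueError("bx = 0 for some instrument; ratio undefined")
    return by / bx, bx**2 / sy**2


def ivw(data: HarmonizedDataset, model: str = "multiplicative-re") -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    ``model='fixed'`` uses the fixed-effect SE; the default
    ``'multiplicative-re'`` inflates it by ``max(1, sqrt(Q/(J-1)))`` so that
    heterogeneity beyond sampling noise widens the interval but can never
    shrink it below the fixed-effect one.
    """
    bx, sx, by, sy = _univariable(data)
    j = len(bx)
    if j == 0:
        raise ValueError("empty dataset")
    if j == 1:
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        est.method = f"ivw ({model})"
        est.q_df = 0
        return est
    if model not in ("fixed", "multiplicative-re"):
        raise ValueError(f"unknown IVW model {model!r}")
    w = bx**2 / sy**2
    if np.all(bx == 0):
        raise ValueError("all bx are zero; IVW degenerate")
    sxx = float(np.sum(bx**2 / sy**2))
    beta = float(np.sum(bx * by / sy**2)) / sxx
    se_fixed = sxx**-0.5
    r = by / bx
    q = float(np.sum(w * (r - beta) ** 2))
    q_df = j - 1
    q_p = float(stats.chi2.sf(q, q_df))
    se = se_fixed if model == "fixed" else se_fixed * max(1.0, math.sqrt(q / q_df))
    return MREstimate(
        method=f"ivw ({model})", beta=beta, se=se, n_snp=j, q=q, q_df=q_df, q_p=q_p
    )


def egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger: weighted regression of ``by`` on ``bx`` with a free intercept.

    Instruments are first oriented so every ``bx`` is non-negative (Egger is
    not invariant to per-SNP joint sign flips without this convention). The
    intercept is the directional-pleiotropy test; large deviations from zero
    indicate exclusion-restriction violations. Both SEs carry a residual
    scale factor floored at 1 (under-dispersion never narrows the interval);
    p-values use t with J-2 degrees of freedom.
    """
    bx, sx, by, sy = _univariable(data)
    j = len(bx)
    if j < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {j}")
    flip = np.where(bx < 0, -1.0, 1.0)
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    # weighted normal equations with intercept
    sw = w.sum()
    mx = float(np.sum(w * x) / sw)
    my = float(np.sum(w * y) / sw)
    sxx = float(np.sum(w * (x - mx) ** 2))
    sxy = float(np.sum(w * (x - mx) * (y - my)))
    if sxx == 0:
        raise ValueError("no spread in |bx|; Egger slope unidentified")
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    df = j - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    scale = max(1.0, sigma2)
    se_slope = math.sqrt(scale / sxx)
    se_int = math.sqrt(scale * (1.0 / sw + mx**2 / sxx))
    p_slope = 2 * float(stats.t.sf(abs(slope) / se_slope, df))
    p_int = 2 * float(stats.t.sf(abs(intercept) / se_int, df))
    tcrit = float(stats.t.ppf(0.975, df))
    q = float(np.sum(w * resid**2))
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        n_snp=j,
        pvalue=p_slope,
        ci_low=slope - tcrit * se_slope,
        ci_high=slope + tcrit * se_slope,
        q=q,
        q_df=df,
        q_p=float(stats.chi2.sf(q, df)),
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th weighted percentile of ordered ratio estimates.

    Cumulative weights are evaluated at interval midpoints
    (cumsum(w) - w/2, normalized), then the estimate is linearly
    interpolated at cumulative weight 0.5.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 5000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Per-SNP ratios ``by/bx`` are weighted by ``bx^2/sy^2``; the estimate is
    the interpolated weighted median, valid if >= 50% of the weight comes
    from valid instruments. The SE is the SD of the estimate over ``n_boot``
    parametric resamples of (bx, by) from normal(observed, se).
    """
    bx, sx, by, sy = _univariable(data)
    j = len(bx)
    if j < 3:
        raise ValueError(f"weighted median requires at least 3 instruments, got {j}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    ratios, weights = _ratio_weights(bx, by, sy)
    point = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    r_star = by_star / bx_star
    w_star = bx_star**2 / sy**2
    order = np.argsort(r_star, axis=1)
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    # vectorized linear interpolation at 0.5 per replicate
    idx = np.argmax(cum >= 0.5, axis=1)
    ests = np.empty(n_boot)
    at_edge = (cum[:, 0] >= 0.5)
    ests[at_edge] = r_sorted[at_edge, 0]
    mid = ~at_edge
    i1 = idx[mid]
    i0 = i1 - 1
    rows = np.flatnonzero(mid)
    c0 = cum[rows, i0]
    c1 = cum[rows, i1]
    ests[mid] = r_sorted[rows, i0] + (0.5 - c0) / (c1 - c0) * (
        r_sorted[rows, i1] - r_sorted[rows, i0]
    )
    se = float(np.std(ests, ddof=1))
    return MREstimate(
        method="weighted_median",
        beta=point,
        se=se,
        n_snp=j,
        extra={"n_boot": n_boot, "seed": seed},
    )


def cochran_q(data: HarmonizedDataset, beta_ref: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around a reference estimate.

    ``Q = sum_j w_j (r_j - beta_ref)^2`` with ratio estimates and weights as
    in the weighted median; df = J - 1; upper-tail chi-square p. Q-p < 0.05
    flags significant heterogeneity among instruments.
    """
    bx, sx, by, sy = _univariable(data)
    ratios, weights = _ratio_weights(bx, by, sy)
    q = float(np.sum(weights * (ratios - beta_ref) ** 2))
    df = len(bx) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def leave_one_out(
    data: HarmonizedDataset, model: str = "multiplicative-re", alpha: float = 0.05
) -> list[dict]:
    """IVW recomputed J times, each time excluding one SNP.

    A SNP is flagged influential when its removal moves the estimate's
    p-value across ``alpha`` or flips the sign of the point estimate.
    """
    full = ivw(data, model=model)
    out = []
    for snp in list(data.snp_ids):
        est = ivw(data.drop_snps([snp]), model=model)
        flag = (est.pvalue < alpha) != (full.pvalue < alpha) or (
            np.sign(est.beta) != np.sign(full.beta)
        )
        out.append({"dropped": snp, "estimate": est, "flagged": bool(flag)})
    return out


def funnel_data(data: HarmonizedDataset) -> "pd.DataFrame":
    """Plot-ready funnel table: per-SNP ratio estimate and precision 1/se."""
    import pandas as pd

    bx, sx, by, sy = _univariable(data)
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    return pd.DataFrame(
        {"SNP": data.snp_ids, "ratio": ratios, "precision": 1.0 / se_ratio}
    )


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, 95% CI low, high)."""
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)
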