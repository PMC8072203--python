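"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier tests.

The framework fits the zero-intercept inverse-variance-weighted model and
asks whether the observed scatter of outcome effects around it is larger
than sampling noise alone would produce:

1. *Global test* — the observed residual sum of squares (RSS), computed
   predictively with leave-one-out slopes, is compared against its null
   distribution built by re-simulating the summary data from the fitted
   model; a small p indicates horizontal pleiotropy somewhere in the set.
2. *Outlier test* — each SNP's own residual contribution is compared against
   its simulated distribution; SNPs significant after Bonferroni correction
   are flagged as pleiotropic outliers.
3. *Distortion test* — when outliers exist, the shift between the raw and
   outlier-removed causal estimates is compared against the distribution of
   shifts produced by removing random same-size SNP subsets.

Tests 2 and 3 are only meaningful when the global test is significant; the
implementation runs them whenever ``global_p < 0.05``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .harmonize import HarmonizedDataset
from .uvmr import MREstimate, ivw

__all__ = ["PressoResult", "presso"]


@dataclass(slots=True)
class PressoResult:
    rss_observed: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: list[str]
    raw_estimate: MREstimate
    corrected_estimate: MREstimate | None = None
    distortion_p: float | None = None
    settings: dict = field(default_factory=dict)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope excluding each SNP in turn (vectorized).

    With S_xy = sum(w bx by) and S_xx = sum(w bx^2), the slope leaving out
    SNP j is (S_xy - w_j bx_j by_j) / (S_xx - w_j bx_j^2).
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    sig: float = 0.05,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Parameters
    ----------
    data:
        Harmonized single-exposure dataset with J >= 4 instruments.
    n_sim:
        Number of simulated datasets for the null RSS distribution.
    seed:
        Mandatory seed; the whole result is reproducible given it.
    sig:
        Family-wise outlier alpha; each SNP is tested at ``sig / J``
        (Bonferroni).
    """
    if seed is None:
        raise ValueError("presso requires an explicit seed")
    bx, sx, by, sy = data.univariable(0)
    if data.n_exposures != 1:
        raise ValueError("MR-PRESSO is univariable; got a multi-exposure dataset")
    j = len(bx)
    if j < 4:
        raise ValueError(f"MR-PRESSO requires at least 4 instruments, got {j}")
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    # simulate under the fitted (leave-one-out predictive) model
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(slopes_loo * bx, sy, size=(n_sim, j))
    slopes_star = _loo_slopes(bx_star, by_star, w)
    resid_star = w * (by_star - slopes_star * bx_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_p = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)

    # per-SNP outlier p from each SNP's simulated residual distribution
    p_per_snp = (1.0 + np.sum(resid_star >= resid_obs[None, :], axis=0)) / (n_sim + 1.0)
    outlier_p = {s: float(p) for s, p in zip(data.snp_ids, p_per_snp)}

    raw = ivw(data, model="fixed")
    result = PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=[],
        raw_estimate=raw,
        settings={"n_sim": n_sim, "seed": seed, "sig": sig},
    )
    if global_p >= sig:
        return result

    threshold = sig / j
    outliers = [s for s, p in outlier_p.items() if p < threshold]
    result.outliers = outliers
    if not outliers:
        return result
    if len(outliers) == j:
        raise ValueError("all instruments flagged as outliers; corrected estimate undefined")

    keep = data.drop_snps(outliers)
    corrected = ivw(keep, model="fixed")
    result.corrected_estimate = corrected

    # distortion: displacement vs removal of random same-size subsets
    n_out = len(outliers)
    d_obs = corrected.beta - raw.beta
    disp = np.empty(n_sim)
    idx_all = np.arange(j)
    sxy_all = np.sum(w * bx * by)
    sxx_all = np.sum(w * bx**2)
    for i in range(n_sim):
        drop = rng.choice(idx_all, size=n_out, replace=False)
        sxy = sxy_all - np.sum(w[drop] * bx[drop] * by[drop])
        sxx = sxx_all - np.sum(w[drop] * bx[drop] ** 2)
        disp[i] = sxy / sxx - raw.beta
    result.distortion_p = (1.0 + float(np.sum(np.abs(disp) >= abs(d_obs)))) / (n_sim + 1.0)
    return result
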