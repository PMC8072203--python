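"""Bayesian model averaging for multivariable Mendelian randomization (MR-BMA).

Multiple correlated exposures (here: NMR metabolite measures) share a pool of
genetic instruments. MR-BMA treats "which exposures are causal" as a model
selection problem: every subset S of exposures defines a weighted linear
model of the outcome effects,

    by_j = sum_{k in S} theta_k bx_jk + eps_j,   eps_j ~ N(0, sy_j^2),

with independent normal priors theta_k ~ N(0, sigma2) and an independent
Bernoulli(prior_p) inclusion prior per exposure. The marginal likelihood of
each subset is available in closed form, so the posterior over subsets, the
per-exposure marginal inclusion probability (MIP) and the model-averaged
causal effect (MACE, shrunk toward zero by construction) follow directly.

Before fitting, rows are transformed to unit outcome variance (divide by
sy) and each exposure column is standardized to unit weighted norm so that
one prior variance is comparable across exposures.

Exposures with near-perfect genetic correlation are statistically
indistinguishable in this framework; ``prune_by_rg`` removes them up front.
Per-model influence diagnostics (per-SNP Q contributions and Cook's
distance) guard the top models against single-instrument artifacts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import HarmonizedDataset

__all__ = [
    "RgMatrix",
    "BMAResult",
    "ModelDiagnostics",
    "prune_by_rg",
    "log_marginal_likelihood",
    "bma",
    "model_diagnostics",
    "rerun_without",
]


@dataclass(slots=True)
class RgMatrix:
    """Symmetric pairwise genetic-correlation matrix with unit diagonal."""

    exposure_ids: list[str]
    rg: np.ndarray

    def __post_init__(self) -> None:
        self.rg = np.asarray(self.rg, float)
        k = len(self.exposure_ids)
        if self.rg.shape != (k, k):
            raise ValueError("rg matrix shape does not match exposure_ids")
        if not np.allclose(self.rg, self.rg.T, atol=1e-8):
            raise ValueError("rg matrix is not symmetric")
        if np.any(np.abs(self.rg) > 1 + 1e-8):
            raise ValueError("genetic correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.rg), 1.0, atol=1e-8):
            raise ValueError("rg diagonal must be 1")

    @classmethod
    def from_tsv(cls, path: str) -> "RgMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(exposure_ids=list(df.index), rg=df.to_numpy())

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.rg, index=self.exposure_ids, columns=self.exposure_ids).to_csv(
            path, sep="\t"
        )


@dataclass(slots=True)
class BMAResult:
    exposure_ids: list[str]
    mip: np.ndarray
    mace: np.ndarray
    #: ranked (subset of exposure_ids, posterior probability, {exposure: theta_hat})
    models: list[tuple[tuple[str, ...], float, dict[str, float]]]
    settings: dict = field(default_factory=dict)

    def ranking(self) -> pd.DataFrame:
        """Exposures ranked by descending marginal inclusion probability."""
        df = pd.DataFrame(
            {"exposure": self.exposure_ids, "mip": self.mip, "mace": self.mace}
        )
        return df.sort_values("mip", ascending=False, kind="mergesort").reset_index(drop=True)

    def model_table(self) -> pd.DataFrame:
        rows = [
            {"model": ",".join(s), "pp": pp, "n_exposures": len(s)}
            for s, pp, _ in self.models
        ]
        return pd.DataFrame(rows)

    def top_models(self, pp_min: float = 0.1) -> list[tuple[tuple[str, ...], float, dict[str, float]]]:
        return [(s, pp, th) for s, pp, th in self.models if pp > pp_min and s]


@dataclass(slots=True)
class ModelDiagnostics:
    model: tuple[str, ...]
    snp_ids: list[str]
    q: np.ndarray
    cooks_distance: np.ndarray
    q_max: float
    cd_max: float

    @property
    def flags(self) -> list[str]:
        mask = (self.q > self.q_max) | (self.cooks_distance > self.cd_max)
        return [s for s, m in zip(self.snp_ids, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "q": self.q,
                "cooks_distance": self.cooks_distance,
                "flagged": (self.q > self.q_max) | (self.cooks_distance > self.cd_max),
            }
        )


def prune_by_rg(
    rg: RgMatrix, priority: dict[str, float], threshold: float = 0.95
) -> list[str]:
    """Prune near-duplicate exposures by genetic correlation.

    While any off-diagonal |rg| above ``threshold`` remains among kept
    exposures, the most correlated pair is found and its lower-priority
    member dropped (ties broken lexicographically by exposure id, dropping
    the later one). ``priority`` is a per-exposure score such as the
    univariable IVW |z| or the instrument count.
    """
    missing = set(rg.exposure_ids) - set(priority)
    if missing:
        raise ValueError(f"priority missing for exposure(s): {sorted(missing)}")
    kept = list(rg.exposure_ids)
    index = {e: i for i, e in enumerate(rg.exposure_ids)}
    while True:
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(sorted(kept), 2):
            r = abs(rg.rg[index[a], index[b]])
            if r > threshold and (best is None or r > best[0]):
                best = (r, a, b)
        if best is None:
            return kept
        _, a, b = best
        if priority[a] < priority[b]:
            drop = a
        elif priority[b] < priority[a]:
            drop = b
        else:
            drop = max(a, b)
        kept.remove(drop)


def _design(data: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-sy transform plus unit-weighted-norm column standardization.

    Returns (X, y, col_norms): X is J x K with unit-norm columns, y = by/sy.
    """
    sy = data.se_outcome
    y = data.beta_outcome / sy
    x = data.beta_exposure / sy[:, None]
    norms = np.linalg.norm(x, axis=0)
    if np.any(norms == 0):
        zero = [e for e, nz in zip(data.exposure_ids, norms == 0) if nz]
        raise ValueError(f"exposure(s) with all-zero weighted effects: {zero}")
    return x / norms, y, norms


def _log_ml_transformed(x: np.ndarray, y: np.ndarray, sigma2: float) -> float:
    """Closed-form log marginal likelihood of y ~ N(X theta, I), theta ~ N(0, sigma2 I).

    Uses the Woodbury/Sylvester identities so only a |S| x |S| system is
    solved: log|I + sigma2 X X'| = log|I_m + sigma2 X'X| and
    y'(I + sigma2 XX')^{-1} y = y'y - sigma2 y'X (I_m + sigma2 X'X)^{-1} X'y.
    """
    j = len(y)
    yy = float(y @ y)
    if x.shape[1] == 0:
        return -0.5 * j * math.log(2 * math.pi) - 0.5 * yy
    m = x.shape[1]
    xtx = x.T @ x
    xty = x.T @ y
    a = np.eye(m) + sigma2 * xtx
    sign, logdet = np.linalg.slogdet(a)
    if sign <= 0:  # cannot occur for sigma2 > 0; guarded anyway
        raise np.linalg.LinAlgError("non-positive-definite prior-weighted Gram matrix")
    quad = yy - sigma2 * float(xty @ np.linalg.solve(a, xty))
    return -0.5 * j * math.log(2 * math.pi) - 0.5 * logdet - 0.5 * quad


def log_marginal_likelihood(
    subset: tuple[int, ...] | list[int],
    data: HarmonizedDataset,
    sigma2: float = 0.25,
) -> float:
    """Log marginal likelihood of an exposure subset (columns by index).

    The empty subset is the null model ``by = eps``. Rows are weighted by
    1/sy^2 and exposure columns standardized to unit weighted norm before
    the closed-form integral over theta ~ N(0, sigma2 I) is evaluated.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x, y, _ = _design(data)
    cols = np.asarray(sorted(subset), int)
    return _log_ml_transformed(x[:, cols], y, sigma2)


def _posterior_mean(x: np.ndarray, y: np.ndarray, sigma2: float) -> np.ndarray:
    """Ridge-type posterior mean theta_hat = (X'X + I/sigma2)^{-1} X'y."""
    m = x.shape[1]
    return np.linalg.solve(x.T @ x + np.eye(m) / sigma2, x.T @ y)


def bma(
    data: HarmonizedDataset,
    prior_p: float = 0.1,
    sigma2: float = 0.25,
    mode: str = "auto",
    z: int = 10000,
    seed: int | None = None,
) -> BMAResult:
    """Bayesian model averaging over exposure subsets.

    Posterior over subsets: pp(S) proportional to
    ``prior_p^|S| (1-prior_p)^(K-|S|) * ML(S)``, normalized over the models
    considered. ``mode='exhaustive'`` enumerates all 2^K subsets (exact
    posterior; the default for K <= 16); ``'shotgun'`` runs a seeded
    stochastic search with add/delete/swap moves for ``z`` iterations and
    normalizes over the distinct models visited. Per exposure,
    MIP_k = sum of pp over models containing k and
    MACE_k = sum over models of pp * posterior-mean effect (zero when the
    exposure is excluded) — the shrinkage that biases MACE toward the null.

    The fit runs on unit-weighted-norm exposure columns (so one prior
    variance is comparable across exposures); conditional estimates and MACE
    are mapped back to the original scale (log-odds per SD of exposure).
    """
    k = data.n_exposures
    if k < 2:
        raise ValueError("bma requires >= 2 exposures; use the univariable estimators")
    if not 0 < prior_p < 1:
        raise ValueError("prior_p must be in (0, 1)")
    if mode == "auto":
        mode = "exhaustive" if k <= 16 else "shotgun"
    x, y, norms = _design(data)

    def log_post(cols: tuple[int, ...]) -> float:
        lp = len(cols) * math.log(prior_p) + (k - len(cols)) * math.log(1 - prior_p)
        return lp + _log_ml_transformed(x[:, list(cols)], y, sigma2)

    visited: dict[tuple[int, ...], float] = {}
    if mode == "exhaustive":
        for size in range(k + 1):
            for cols in itertools.combinations(range(k), size):
                visited[cols] = log_post(cols)
    elif mode == "shotgun":
        if seed is None:
            raise ValueError("shotgun mode requires an explicit seed")
        rng = np.random.default_rng(seed)
        current: tuple[int, ...] = tuple(sorted(rng.choice(k, size=1)))
        visited[current] = log_post(current)
        visited[()] = log_post(())
        for _ in range(z):
            cur = set(current)
            move = rng.integers(3)
            prop = set(cur)
            if move == 0 and len(cur) < k:  # add
                prop.add(int(rng.choice(sorted(set(range(k)) - cur))))
            elif move == 1 and cur:  # delete
                prop.discard(int(rng.choice(sorted(cur))))
            elif move == 2 and cur and len(cur) < k:  # swap
                prop.discard(int(rng.choice(sorted(cur))))
                prop.add(int(rng.choice(sorted(set(range(k)) - cur))))
            prop_t = tuple(sorted(prop))
            if prop_t == current:
                continue
            if prop_t not in visited:
                visited[prop_t] = log_post(prop_t)
            if math.log(rng.random()) < visited[prop_t] - visited[current]:
                current = prop_t
    else:
        raise ValueError(f"unknown mode {mode!r}")

    keys = list(visited)
    logs = np.array([visited[s] for s in keys])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()

    mip = np.zeros(k)
    mace = np.zeros(k)
    models: list[tuple[tuple[str, ...], float, dict[str, float]]] = []
    for cols, pp in zip(keys, probs):
        theta = {}
        if cols:
            th = _posterior_mean(x[:, list(cols)], y, sigma2)
            th = th / norms[list(cols)]  # back to log-odds per SD of exposure
            theta = {data.exposure_ids[c]: float(t) for c, t in zip(cols, th)}
            for c, t in zip(cols, th):
                mip[c] += pp
                mace[c] += pp * t
        models.append((tuple(data.exposure_ids[c] for c in cols), float(pp), theta))
    models.sort(key=lambda m: -m[1])
    return BMAResult(
        exposure_ids=list(data.exposure_ids),
        mip=mip,
        mace=mace,
        models=models,
        settings={
            "prior_p": prior_p,
            "sigma2": sigma2,
            "mode": mode,
            "z": z,
            "seed": seed,
        },
    )


def model_diagnostics(
    subset: tuple[str, ...] | list[str],
    data: HarmonizedDataset,
    q_max: float = 10.0,
    cd_max: float | None = None,
) -> ModelDiagnostics:
    """Per-SNP heterogeneity (Q contribution) and Cook's distance for one model.

    The subset model is fit by weighted least squares (in the transformed,
    unit-outcome-variance space). For SNP j,
    ``q_j = (by_j - yhat_j)^2 / sy_j^2`` and ``cd_j`` is the standard
    leverage-form Cook's distance — identical to the scaled shift in fitted
    values when observation j is deleted. Default flag thresholds are
    q > 10 and cd > 4/J.
    """
    idx = [data.exposure_ids.index(e) for e in subset]
    if not idx:
        raise ValueError("diagnostics need a non-empty exposure subset")
    x_all, y, _ = _design(data)
    x = x_all[:, idx]
    j, p = x.shape
    if cd_max is None:
        cd_max = 4.0 / j
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ coef
    resid = y - yhat
    q = resid**2
    hat = x @ np.linalg.solve(x.T @ x, x.T)
    h = np.diag(hat)
    s2 = float(resid @ resid) / (j - p) if j > p else float("nan")
    # a numerically perfect fit has no residual scale; report zero influence
    negligible = s2 <= 1e-24 * (float(y @ y) / j + 1e-300)
    if negligible or math.isnan(s2):
        cd = np.zeros(j) if negligible else np.full(j, float("nan"))
    else:
        cd = resid**2 * h / (p * s2 * (1 - h) ** 2)
    return ModelDiagnostics(
        model=tuple(subset),
        snp_ids=list(data.snp_ids),
        q=q,
        cooks_distance=cd,
        q_max=q_max,
        cd_max=cd_max,
    )


def rerun_without(
    data: HarmonizedDataset,
    snp_ids: list[str],
    **bma_settings,
) -> BMAResult:
    """Re-run BMA with the given SNPs omitted (influential-point sensitivity)."""
    sub = data.drop_snps(list(snp_ids))
    if sub.n_snps < sub.n_exposures + 2:
        raise ValueError(
            f"{sub.n_snps} SNP(s) remain after dropping {len(snp_ids)}; "
            f"model with {sub.n_exposures} exposures unidentifiable"
        )
    return bma(sub, **bma_settings)
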