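"""Effective-number-of-tests correction for correlated outcomes.

Testing K correlated metabolites is less than K independent tests. The
eigenvalue spectrum of their correlation matrix measures how much: perfectly
correlated traits contribute one effective test, independent ones contribute
K. The Li & Ji convention counts, per eigenvalue lambda,
``I(lambda >= 1) + (lambda - floor(lambda))``; Nyholt's earlier variant
``1 + (K - 1) (1 - var(lambda)/K)`` is available as a flag. The adjusted
significance threshold is alpha divided by the effective test count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationMatrix", "effective_tests", "adjusted_threshold"]


@dataclass(slots=True)
class CorrelationMatrix:
    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        k = len(self.labels)
        if self.r.shape != (k, k):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("correlation diagonal must be 1")

    @classmethod
    def from_tsv(cls, path: str) -> "CorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=list(df.index), r=df.to_numpy())


def effective_tests(corr: CorrelationMatrix, method: str = "li-ji") -> float:
    """Effective number of independent tests among correlated traits.

    Always in [1, K]; equals K for the identity matrix and 1 when all traits
    are perfectly correlated.
    """
    lam = np.linalg.eigvalsh(corr.r)
    if lam.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    # snap eigenvalues sitting on integers (block structures) before floor
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9, near, lam)
    if method == "li-ji":
        return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    if method == "nyholt":
        k = len(lam)
        return float(1 + (k - 1) * (1 - lam.var(ddof=1) / k))
    raise ValueError(f"unknown method {method!r}")


def adjusted_threshold(alpha: float, meff: float) -> tuple[float, float]:
    """Significance threshold adjusted for the effective test count.

    Returns (full-precision threshold, the same rounded to two significant
    figures for reporting).
    """
    if alpha <= 0 or meff <= 0:
        raise ValueError("alpha and meff must be positive")
    t = alpha / meff
    exponent = math.floor(math.log10(abs(t)))
    rounded = round(t, -exponent + 1)
    return t, rounded
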