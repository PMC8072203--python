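import numpy as np
import pytest

from mrkit import SimConfig, simulate_two_sample
from mrkit.harmonize import HarmonizedDataset
from mrkit.synth import to_harmonized


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(
    bx, sx, by, sy, snp_ids=None, exposure_ids=("x",)
) -> HarmonizedDataset:
    """Hand-assemble a univariable or multivariable harmonized dataset."""
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1 and len(np.atleast_1d(by)) > 1:
        bx = bx.T
    sx = np.atleast_2d(np.asarray(sx, float))
    if sx.shape == bx.T.shape and sx.shape != bx.shape:
        sx = sx.T
    if sx.shape != bx.shape:
        sx = np.broadcast_to(sx.reshape(-1)[:, None] if sx.size == bx.shape[0] else sx, bx.shape).copy()
    j = bx.shape[0]
    return HarmonizedDataset(
        snp_ids=list(snp_ids) if snp_ids else [f"rs{i}" for i in range(j)],
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=np.asarray(by, float),
        se_outcome=np.asarray(sy, float),
        exposure_ids=list(exposure_ids),
    )


@pytest.fixture
def seeded_dataset():
    """A 10-SNP univariable dataset with true causal effect 0.3."""
    cfg = SimConfig(J=10, K=1, theta=0.3, seed=42)
    exposures, outcome, truth = simulate_two_sample(cfg)
    return to_harmonized(exposures, outcome)


@pytest.fixture
def random_dataset(rng):
    """12 SNPs with heterogeneous ratios and unequal weights (no structure)."""
    j = 12
    bx = rng.uniform(0.05, 0.2, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.005, 0.03, j)
    return make_dataset(bx, sx, by, sy)
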