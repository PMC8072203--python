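import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrkit import uvmr
from mrkit.uvmr import (
    cochran_q,
    egger,
    funnel_data,
    ivw,
    leave_one_out,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from .conftest import make_dataset


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.05, 0.25, 0.1)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_numerator(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.1)
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.05, 0.2, 0.1)

    @pytest.mark.parametrize(
        "bx,sx,by,sy",
        [(0.5, 0.02, 0.1, 0.05), (-0.3, 0.01, 0.06, 0.02), (0.12, 0.01, -0.02, 0.008),
         (1.5, 0.1, 0.4, 0.2), (-0.08, 0.005, -0.02, 0.01)],
    )
    def test_matches_delta_method(self, bx, sx, by, sy):
        # first-order delta method for g(y) = y / c with c = bx fixed:
        # Var(g) = sy^2 / bx^2
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(by / bx)
        assert est.se == pytest.approx(math.sqrt(sy**2 / bx**2))


class TestIVW:
    def test_identical_ratios_give_zero_q(self):
        data = make_dataset([0.1, 0.2], 0.01, [0.05, 0.10], [0.01, 0.01])
        est = ivw(data)
        assert est.beta == pytest.approx(0.5)
        assert est.q == pytest.approx(0.0, abs=1e-24)

    def test_single_snp_reduces_to_wald(self):
        data = make_dataset([0.1], [0.01], [0.05], [0.02])
        est = ivw(data)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_matches_zero_intercept_wls_oracle(self, random_dataset):
        bx, sx, by, sy = random_dataset.univariable(0)
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        est_fixed = ivw(random_dataset, model="fixed")
        assert est_fixed.beta == pytest.approx(float(fit.params[0]), rel=1e-10)
        se_oracle = math.sqrt(1.0 / np.sum(bx**2 / sy**2))
        assert est_fixed.se == pytest.approx(se_oracle, rel=1e-10)

    def test_multiplicative_re_floors_at_fixed(self, random_dataset):
        fixed = ivw(random_dataset, model="fixed")
        mre = ivw(random_dataset, model="multiplicative-re")
        assert mre.beta == pytest.approx(fixed.beta)
        assert mre.se >= fixed.se - 1e-15
        assert mre.se == pytest.approx(
            fixed.se * max(1.0, math.sqrt(fixed.q / fixed.q_df))
        )

    def test_invariant_to_order_and_joint_sign_flip(self, random_dataset):
        d = random_dataset
        est = ivw(d, model="fixed")
        perm = np.arange(d.n_snps)[::-1]
        d2 = make_dataset(
            d.beta_exposure[perm], d.se_exposure[perm],
            d.beta_outcome[perm], d.se_outcome[perm],
        )
        d2.beta_exposure[0] *= -1
        d2.beta_outcome[0] *= -1
        est2 = ivw(d2, model="fixed")
        assert est2.beta == pytest.approx(est.beta, rel=1e-12)
        assert est2.q == pytest.approx(est.q, rel=1e-12)

    def test_rejects_all_zero_bx(self):
        data = make_dataset([0.0, 0.0], 0.01, [0.1, 0.1], [0.01, 0.01])
        with pytest.raises(ValueError):
            ivw(data)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.1 + 0.4 * bx
        data = make_dataset(bx, 0.01, by, np.full(4, 0.02))
        est = egger(data)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_with_intercept_oracle(self, random_dataset):
        bx, sx, by, sy = random_dataset.univariable(0)
        flip = np.sign(bx)
        x, y = bx * flip, by * flip
        fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
        est = egger(random_dataset)
        assert est.beta == pytest.approx(float(fit.params[1]), rel=1e-10)
        assert est.intercept == pytest.approx(float(fit.params[0]), rel=1e-10)
        scale_floor = max(1.0, math.sqrt(float(fit.mse_resid)))
        se_oracle = float(fit.bse[1]) / math.sqrt(float(fit.mse_resid)) * scale_floor
        assert est.se == pytest.approx(se_oracle, rel=1e-10)

    def test_orientation_invariance(self, random_dataset):
        d = random_dataset
        ref = egger(d)
        d.beta_exposure[3] *= -1
        d.beta_outcome[3] *= -1
        flipped = egger(d)
        assert flipped.beta == pytest.approx(ref.beta, rel=1e-12)
        assert flipped.intercept == pytest.approx(ref.intercept, rel=1e-12)

    def test_requires_three_instruments(self):
        data = make_dataset([0.1, 0.2], 0.01, [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(ValueError):
            egger(data)


class TestWeightedMedian:
    def test_constant_ratios(self):
        data = make_dataset([0.1, 0.2, 0.4], 0.01, [0.07, 0.14, 0.28], [0.01, 0.05, 0.02])
        est = weighted_median(data, n_boot=200, seed=7)
        assert est.beta == pytest.approx(0.7)

    def test_symmetric_interpolation(self):
        # ratios (1, 2, 3) with equal weights: midpoint cumulative weights
        # (1/6, 1/2, 5/6) put the 50th percentile exactly at 2
        data = make_dataset([0.1, 0.1, 0.1], 0.01, [0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        est = weighted_median(data, n_boot=200, seed=7)
        assert est.beta == pytest.approx(2.0)

    def test_matches_segment_scan_oracle(self, rng):
        j = 9
        bx = rng.uniform(0.05, 0.2, j)
        by = rng.normal(0.3 * bx, 0.03)
        sy = rng.uniform(0.01, 0.05, j)
        data = make_dataset(bx, 0.01, by, sy)
        est = weighted_median(data, n_boot=200, seed=11)

        # brute-force oracle: scan every interpolation segment
        r = by / bx
        w = bx**2 / sy**2
        order = np.argsort(r)
        r, w = r[order], w[order] / w.sum()
        cum = np.cumsum(w) - w / 2
        oracle = None
        if cum[0] >= 0.5:
            oracle = r[0]
        for i in range(j - 1):
            if cum[i] <= 0.5 <= cum[i + 1]:
                oracle = r[i] + (0.5 - cum[i]) * (r[i + 1] - r[i]) / (cum[i + 1] - cum[i])
                break
        else:
            if oracle is None:
                oracle = r[-1]
        assert est.beta == pytest.approx(float(oracle), rel=1e-12)

    def test_bootstrap_se_stable_across_seeds(self, seeded_dataset):
        ses = [
            weighted_median(seeded_dataset, n_boot=5000, seed=s).se for s in (1, 2, 3)
        ]
        assert max(ses) / min(ses) < 1.1

    def test_seed_mandatory(self, seeded_dataset):
        with pytest.raises(ValueError):
            weighted_median(seeded_dataset)


class TestCochranQ:
    def test_identical_ratios(self):
        data = make_dataset([0.1, 0.2], 0.01, [0.05, 0.1], [0.01, 0.01])
        q, df, p = cochran_q(data, 0.5)
        assert q == pytest.approx(0.0, abs=1e-24)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_hand_arithmetic(self):
        # ratios 0 and 1, weights w = bx^2/sy^2 = 1 each, beta_ref 0.5:
        # Q = 1*(0-0.5)^2 + 1*(1-0.5)^2 = 0.5
        data = make_dataset([1.0, 1.0], 0.1, [0.0, 1.0], [1.0, 1.0])
        q, df, _ = cochran_q(data, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1


class TestLeaveOneOut:
    def test_two_snps_reduce_to_wald(self):
        data = make_dataset([0.1, 0.2], [0.01, 0.01], [0.05, 0.12], [0.01, 0.015])
        res = leave_one_out(data)
        assert res[0]["estimate"].beta == pytest.approx(
            wald_ratio(0.2, 0.01, 0.12, 0.015).beta
        )
        assert res[1]["estimate"].beta == pytest.approx(
            wald_ratio(0.1, 0.01, 0.05, 0.01).beta
        )

    def test_homogeneous_set_no_flags(self, seeded_dataset):
        assert not any(r["flagged"] for r in leave_one_out(seeded_dataset))

    def test_planted_outlier_flagged(self, seeded_dataset):
        d = seeded_dataset
        # push the whole estimate across significance via one extreme SNP
        d2 = make_dataset(
            d.beta_exposure, d.se_exposure, d.beta_outcome - 0.3 * d.beta_exposure[:, 0],
            d.se_outcome,
        )  # null out the signal...
        d2.beta_outcome[0] += 50 * d2.se_outcome[0]  # ...then plant an extreme SNP
        res = leave_one_out(d2, model="fixed")
        flagged = [r["dropped"] for r in res if r["flagged"]]
        assert d2.snp_ids[0] in flagged


class TestFunnelAndOr:
    def test_funnel_rows_and_ratios(self, seeded_dataset):
        t = funnel_data(seeded_dataset)
        assert len(t) == seeded_dataset.n_snps
        bx, sx, by, sy = seeded_dataset.univariable(0)
        np.testing.assert_allclose(t["ratio"], by / bx)
        # precision ordering mirrors 1/se ordering
        se_ratio = sy / np.abs(bx)
        assert list(np.argsort(t["precision"])) == list(np.argsort(-se_ratio))

    def test_odds_ratio(self):
        assert to_odds_ratio(0.0, 0.1)[0] == pytest.approx(1.0)
        or_, lo, hi = to_odds_ratio(math.log(2), 0.0)
        assert or_ == pytest.approx(2.0)
        assert lo == pytest.approx(hi)
        b = 0.37
        assert math.log(to_odds_ratio(b, 0.1)[0]) == pytest.approx(b)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(min_value=0.1, max_value=10.0))
def test_scale_equivariance(c):
    """Rescaling the outcome (by, sy -> c*by, c*sy) rescales beta and se by c."""
    rng = np.random.default_rng(5)
    bx = rng.uniform(0.05, 0.2, 10)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.01, 0.03, 10)
    d1 = make_dataset(bx, 0.01, by, sy)
    d2 = make_dataset(bx, 0.01, c * by, c * sy)
    for method in (
        lambda d: ivw(d, model="fixed"),
        lambda d: ivw(d, model="multiplicative-re"),
        egger,
        lambda d: weighted_median(d, n_boot=300, seed=9),
    ):
        e1, e2 = method(d1), method(d2)
        assert e2.beta == pytest.approx(c * e1.beta, rel=1e-9)
        assert e2.se == pytest.approx(c * e1.se, rel=0.05 if "median" in e1.method else 1e-9)
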