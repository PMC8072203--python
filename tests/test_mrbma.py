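import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from mrkit import SimConfig, simulate_rg, simulate_two_sample
from mrkit.mrbma import (
    RgMatrix,
    bma,
    log_marginal_likelihood,
    model_diagnostics,
    prune_by_rg,
    rerun_without,
)
from mrkit.synth import to_harmonized
from .conftest import make_dataset


def _multi_dataset(seed=5, j=12, k=3, theta=(0.4, 0.0, 0.0)):
    cfg = SimConfig(
        J=j, K=k, theta=list(theta), n_exposure=100000, n_outcome=250000, seed=seed
    )
    return to_harmonized(*simulate_two_sample(cfg)[:2])


class TestPruneByRg:
    def test_identity_keeps_all(self):
        rg = RgMatrix(["a", "b", "c"], np.eye(3))
        assert prune_by_rg(rg, {"a": 1, "b": 2, "c": 3}) == ["a", "b", "c"]

    def test_lower_priority_member_dropped(self):
        rg = RgMatrix(["a", "b"], np.array([[1.0, 0.99], [0.99, 1.0]]))
        assert prune_by_rg(rg, {"a": 3, "b": 5}) == ["b"]

    def test_ties_broken_lexicographically(self):
        rg = RgMatrix(["b", "a"], np.array([[1.0, 0.99], [0.99, 1.0]]))
        assert prune_by_rg(rg, {"a": 1, "b": 1}) == ["a"]

    def test_block_structure_prunes_to_one_per_block(self):
        rg = simulate_rg(6, blocks=2, within_block_rg=0.99, seed=3)
        kept = prune_by_rg(rg, {e: i for i, e in enumerate(rg.exposure_ids)})
        # exposures alternate blocks (round-robin): 2 blocks -> 2 survivors
        assert len(kept) == 2

    def test_threshold_not_crossed_keeps_everything(self):
        rg = simulate_rg(5, blocks=5, within_block_rg=0.9, seed=3)  # identity
        kept = prune_by_rg(rg, {e: 1.0 for e in rg.exposure_ids})
        assert len(kept) == 5


class TestLogMarginalLikelihood:
    def test_null_model_closed_form(self):
        data = make_dataset([0.1, 0.2, 0.15], 0.01, [0.04, 0.09, 0.05], [0.02, 0.03, 0.025])
        y = data.beta_outcome / data.se_outcome
        expected = -0.5 * len(y) * math.log(2 * math.pi) - 0.5 * float(y @ y)
        assert log_marginal_likelihood([], data) == pytest.approx(expected, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        data = make_dataset([0.1, 0.2, 0.15], 0.01, [0.04, 0.09, 0.05], [0.02, 0.03, 0.025])
        sigma2 = 0.25
        # oracle: numerically integrate likelihood x prior over theta using the
        # same transformed, unit-norm design the model defines
        y = data.beta_outcome / data.se_outcome
        x = (data.beta_exposure[:, 0] / data.se_outcome)
        x = x / np.linalg.norm(x)

        def integrand(theta):
            lik = np.prod(stats.norm.pdf(y - x * theta))
            return lik * stats.norm.pdf(theta, scale=math.sqrt(sigma2))

        val, _ = integrate.quad(integrand, -20, 20, limit=200)
        assert log_marginal_likelihood([0], data, sigma2=sigma2) == pytest.approx(
            math.log(val), abs=1e-4
        )

    def test_sigma2_to_zero_approaches_null(self):
        data = make_dataset([0.1, 0.2, 0.15], 0.01, [0.04, 0.09, 0.05], [0.02, 0.03, 0.025])
        null = log_marginal_likelihood([], data)
        assert log_marginal_likelihood([0], data, sigma2=1e-12) == pytest.approx(
            null, abs=1e-5
        )


class TestBMA:
    def test_exhaustive_posteriors_sum_to_one(self):
        data = _multi_dataset(k=4, theta=(0.3, 0.0, 0.0, 0.0))
        res = bma(data, mode="exhaustive")
        total = sum(pp for _, pp, _ in res.models)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert len(res.models) == 2**4

    def test_mip_is_sum_of_pp_over_containing_models(self):
        data = _multi_dataset()
        res = bma(data)
        for k, eid in enumerate(res.exposure_ids):
            mip_oracle = sum(pp for s, pp, _ in res.models if eid in s)
            assert res.mip[k] == pytest.approx(mip_oracle, abs=1e-12)

    def test_causal_exposure_outranks_null(self):
        wins = 0
        for i in range(20):
            data = _multi_dataset(seed=800 + i, k=2, theta=(0.4, 0.0))
            res = bma(data)
            wins += res.mip[0] > res.mip[1]
        assert wins >= 19

    def test_uniform_model_prior_proportional_to_ml(self):
        data = _multi_dataset(k=3, theta=(0.3, 0.0, 0.0))
        res = bma(data, prior_p=0.5)
        logml = {
            s: log_marginal_likelihood(
                [data.exposure_ids.index(e) for e in s], data, sigma2=0.25
            )
            for s, _, _ in res.models
        }
        mx = max(logml.values())
        weights = {s: math.exp(v - mx) for s, v in logml.items()}
        z = sum(weights.values())
        for s, pp, _ in res.models:
            assert pp == pytest.approx(weights[s] / z, rel=1e-9)

    def test_mace_shrinkage_bound(self):
        data = _multi_dataset()
        res = bma(data)
        for k, eid in enumerate(res.exposure_ids):
            max_theta = max(
                (abs(th[eid]) for _, _, th in res.models if eid in th), default=0.0
            )
            assert abs(res.mace[k]) <= max_theta + 1e-12

    def test_label_equivariance(self):
        data = _multi_dataset(k=3, theta=(0.3, 0.1, 0.0))
        res = bma(data)
        perm = [2, 0, 1]
        data2 = make_dataset(
            data.beta_exposure[:, perm],
            data.se_exposure[:, perm],
            data.beta_outcome,
            data.se_outcome,
            exposure_ids=[data.exposure_ids[p] for p in perm],
        )
        res2 = bma(data2)
        for k, p in enumerate(perm):
            assert res2.mip[k] == pytest.approx(res.mip[p], rel=1e-9)
            assert res2.mace[k] == pytest.approx(res.mace[p], rel=1e-9)

    def test_exhaustive_deterministic_and_shotgun_seed_stable(self):
        data = _multi_dataset(k=3)
        a, b = bma(data), bma(data)
        assert [m[:2] for m in a.models] == [m[:2] for m in b.models]
        s1 = bma(data, mode="shotgun", z=2000, seed=4)
        s2 = bma(data, mode="shotgun", z=2000, seed=4)
        np.testing.assert_array_equal(s1.mip, s2.mip)

    def test_shotgun_reproduces_exhaustive_mips(self):
        data = _multi_dataset(seed=9, j=21, k=9, theta=(0.4,) + (0.0,) * 8)
        exact = bma(data, mode="exhaustive")
        shot = bma(data, mode="shotgun", z=10000, seed=12)
        np.testing.assert_allclose(shot.mip, exact.mip, atol=0.02)

    def test_rejects_single_exposure(self):
        data = make_dataset([0.1, 0.2, 0.15], 0.01, [0.04, 0.09, 0.05], [0.02] * 3)
        with pytest.raises(ValueError, match="univariable"):
            bma(data)


class TestDiagnostics:
    def test_perfect_fit_all_zero(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.12])
        data = make_dataset(bx, 0.01, 0.4 * bx, np.full(5, 1.0), exposure_ids=["x"])
        d = model_diagnostics(["x"], data)
        np.testing.assert_allclose(d.q, 0.0, atol=1e-28)
        np.testing.assert_allclose(d.cooks_distance, 0.0, atol=1e-28)

    def test_cooks_distance_matches_delete_one_refit(self, rng):
        j, p = 8, 2
        data = _multi_dataset(seed=31, j=j, k=p, theta=(0.3, 0.1))
        d = model_diagnostics(list(data.exposure_ids), data)

        # brute-force oracle on the same transformed design
        sy = data.se_outcome
        y = data.beta_outcome / sy
        x = data.beta_exposure / sy[:, None]
        x = x / np.linalg.norm(x, axis=0)
        beta_full, *_ = np.linalg.lstsq(x, y, rcond=None)
        yhat = x @ beta_full
        s2 = float((y - yhat) @ (y - yhat)) / (j - p)
        for drop in range(j):
            keep = [i for i in range(j) if i != drop]
            beta_d, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
            cd_oracle = float((x @ beta_full - x @ beta_d) @ (x @ beta_full - x @ beta_d)) / (
                p * s2
            )
            assert d.cooks_distance[drop] == pytest.approx(cd_oracle, rel=1e-10, abs=1e-12)

    def test_default_threshold_is_four_over_j(self):
        data = _multi_dataset(seed=31, j=21, k=2, theta=(0.3, 0.1))
        d = model_diagnostics([data.exposure_ids[0]], data)
        assert d.cd_max == pytest.approx(4.0 / 21.0)
        assert round(d.cd_max, 2) == 0.19


class TestRerunWithout:
    def test_dropping_nothing_is_identity(self):
        data = _multi_dataset()
        a = bma(data)
        b = rerun_without(data, [])
        np.testing.assert_array_equal(a.mip, b.mip)

    def test_max_cd_snp_moves_mips_most(self):
        cfg = SimConfig(J=15, K=2, theta=[0.4, 0.0], seed=77)
        data = to_harmonized(*simulate_two_sample(cfg)[:2])
        # plant an influential point
        data.beta_outcome[0] += 20 * data.se_outcome[0]
        base = bma(data)
        d = model_diagnostics([base.ranking().iloc[0]["exposure"]], data)
        worst = data.snp_ids[int(np.argmax(d.cooks_distance))]
        benign = data.snp_ids[int(np.argmin(d.cooks_distance))]
        shift_worst = np.abs(rerun_without(data, [worst]).mip - base.mip).max()
        shift_benign = np.abs(rerun_without(data, [benign]).mip - base.mip).max()
        assert shift_worst > shift_benign

    def test_identifiability_guard(self):
        data = _multi_dataset(j=5, k=3, theta=(0.3, 0.0, 0.0))
        with pytest.raises(ValueError, match="unidentifiable"):
            rerun_without(data, data.snp_ids[:2])
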