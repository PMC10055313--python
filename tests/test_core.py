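import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from smash._exceptions import ValidationError
from smash.core import (
    SMASH,
    combine_min_p,
    gamma_pvalue,
    rank_results,
    run_smash,
    smash_statistic,
)
from smash.io import SpatialDataset, prepare_expression
from smash.kernels import (
    cosine_kernel,
    data_driven_grid,
    default_battery,
    gaussian_kernel,
    projection_kernel,
)
from smash.simulate import GPConfig, simulate_gp


def _prep(rng, K=5, N=40, d=2):
    Y = rng.standard_normal((K, N))
    ds = SpatialDataset(
        Y - Y.min(axis=1, keepdims=True),
        rng.uniform(0, 1, (N, d)),
        np.array([f"g{i}" for i in range(K)], object),
        np.array([f"s{i}" for i in range(N)], object),
    )
    return prepare_expression(ds), ds


class TestSmashStatistic:
    def test_identity_kernel_gives_one_over_n(self, rng):
        prep, ds = _prep(rng, K=1, N=35)
        km = gaussian_kernel(ds.coords, 1e-9)  # off-diagonals underflow to 0
        T = smash_statistic(prep.residuals[0], prep.sum_sq[0], km)
        np.testing.assert_allclose(T, 1.0 / 35, rtol=1e-12)

    def test_scale_invariance(self, rng):
        prep, ds = _prep(rng, K=1, N=40)
        km = gaussian_kernel(ds.coords, 0.2)
        y = prep.residuals[0]
        T1 = smash_statistic(y, y @ y, km)
        T2 = smash_statistic(-3.5 * y, 3.5**2 * (y @ y), km)
        np.testing.assert_allclose(T1, T2, rtol=1e-12)

    @pytest.mark.parametrize("family", ["gaussian", "cosine", "projection"])
    def test_matches_dense_trace_oracle(self, rng, family):
        # T must equal tr(E_k H)/N with E_k = yyᵀ/(yᵀy) fully materialized
        prep, ds = _prep(rng, K=1, N=40)
        if family == "gaussian":
            km = gaussian_kernel(ds.coords, 0.3)
        elif family == "cosine":
            km = cosine_kernel(ds.coords, 0.5)
        else:
            km = projection_kernel(ds.coords)
        y = prep.residuals[0]
        E = np.outer(y, y) / (y @ y)
        oracle = np.trace(E @ km.dense()) / 40
        T = smash_statistic(y, prep.sum_sq[0], km)
        np.testing.assert_allclose(T, oracle, atol=1e-10)

    def test_degenerate_sum_sq_rejected(self, rng):
        prep, ds = _prep(rng, K=1, N=30)
        km = gaussian_kernel(ds.coords, 0.2)
        with pytest.raises(ValidationError):
            smash_statistic(np.zeros(30), 0.0, km)


class TestGammaPvalue:
    def test_reduces_to_chi_square_one(self):
        # E(T)=1, V(T)=2 ⇔ Gamma(1/2, 2) = χ²₁; p(3.841) ≈ 0.0500
        N = 10
        p = gamma_pvalue(3.841, N**2, N**4, N)
        np.testing.assert_allclose(p, stats.chi2.sf(3.841, 1), rtol=1e-12)
        assert abs(p - 0.05) < 1e-3

    def test_monotone_tail_limits(self, rng):
        N = 50
        tc, tsc = 30.0, 25.0
        ts = np.linspace(1e-8, 0.2, 50)
        ps = gamma_pvalue(ts, tc, tsc, N)
        assert np.all(np.diff(ps) <= 0)
        assert ps[0] > 0.999
        assert gamma_pvalue(1e6, tc, tsc, N) <= 1e-300 * 1.01

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            gamma_pvalue(np.nan, 1.0, 1.0, 10)

    def test_permutation_moments_match_small(self, rng):
        # N=60 sanity check of the asymptotic null against permutations:
        # the exact permutation mean carries an N/(N−1) factor relative to
        # the asymptotic tr(H̃)/N²; the variance formula is accurate to
        # O(1/N) relative and the gamma p-values stay near-uniform
        N, B = 60, 5000
        coords = rng.uniform(0, 1, (N, 2))
        km = gaussian_kernel(coords, 0.2)
        y = rng.standard_normal(N)
        y -= y.mean()
        perms = np.array([rng.permutation(y) for _ in range(B)])
        T = np.einsum("bn,bn->b", perms @ km.dense(), perms) / (N * (y @ y))
        ET_exact = (N / (N - 1)) * km.trace_centered / N**2
        VT = 2 * km.trace_sq_centered / N**4
        assert abs(T.mean() / ET_exact - 1.0) < 0.02
        assert abs(T.var(ddof=1) / VT - 1.0) < 0.2
        p = gamma_pvalue(T, km.trace_centered, km.trace_sq_centered, N)
        assert stats.kstest(p, "uniform").statistic < 0.08


class TestCombineMinP:
    def test_single_and_capped(self):
        assert combine_min_p([0.037]) == pytest.approx(0.037)
        assert combine_min_p([0.01] + [0.5] * 30) == pytest.approx(0.31)
        assert combine_min_p([0.05] + [0.9] * 30) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            combine_min_p([])


class TestRunSmash:
    def test_degenerate_gene_flagged(self, rng):
        Y = rng.standard_normal((3, 50))
        Y[1] = 4.2  # constant gene
        ds = SpatialDataset(
            np.abs(Y),
            rng.uniform(0, 1, (50, 2)),
            np.array(["a", "b", "c"], object),
            np.array([f"s{i}" for i in range(50)], object),
        )
        ds.expression[1] = 4.2
        prep = prepare_expression(ds)
        res = run_smash(prep, default_battery(ds.coords, 3, 3))
        assert [r.degenerate for r in res] == [False, True, False]
        assert res[1].combined_p == 1.0

    def test_null_rejection_conservative(self, rng):
        prep, ds = _prep(rng, K=500, N=200)
        res = run_smash(prep, default_battery(ds.coords, seed=1))
        rej = np.mean([r.combined_p <= 0.05 for r in res])
        assert rej <= 0.07

    def test_signal_gene_detected(self):
        sim = simulate_gp(GPConfig(N=500, K=5, h=0.3, kernel_parameter=0.2, seed=3))
        prep = prepare_expression(sim.dataset)
        res = run_smash(prep, default_battery(sim.dataset.coords, seed=3))
        assert min(r.combined_p for r in res) < 1e-3

    def test_affine_invariance_of_pvalues(self, rng):
        prep, ds = _prep(rng, K=4, N=60)
        bat = default_battery(ds.coords, 3, 3)
        res1 = run_smash(prep, bat)
        ds2 = SpatialDataset(2.5 * ds.expression + 11.0, ds.coords, ds.gene_ids, ds.spot_ids)
        res2 = run_smash(prepare_expression(ds2), bat)
        for a, b in zip(res1, res2):
            np.testing.assert_allclose(a.per_kernel_stat, b.per_kernel_stat, atol=1e-10)
            np.testing.assert_allclose(a.combined_p, b.combined_p, atol=1e-8)

    def test_power_monotone_in_effect_size(self):
        logs = []
        for h in (0.0, 0.1, 0.2, 0.3):
            vals = []
            for rep in range(5):
                sim = simulate_gp(GPConfig(N=250, K=60, h=h, kernel_parameter=0.2, seed=100 + rep))
                prep = prepare_expression(sim.dataset)
                res = run_smash(prep, default_battery(sim.dataset.coords, seed=rep))
                vals.append(np.mean([-np.log10(r.combined_p) for r in res]))
            logs.append(np.mean(vals))
        diffs = np.diff(logs)
        assert np.all(diffs > -0.02)

    def test_ranking_deterministic(self, rng):
        prep, ds = _prep(rng, K=10, N=50)
        res = run_smash(prep, default_battery(ds.coords, 3, 3))
        r1 = [r.gene_id for r in rank_results(res)]
        r2 = [r.gene_id for r in rank_results(list(reversed(res)))]
        assert r1 == r2


class TestEstimatorAPI:
    def test_fit_attributes_and_transform(self, rng):
        N, K = 80, 12
        X = rng.standard_normal((N, K))
        coords = rng.uniform(0, 1, (N, 2))
        est = SMASH(n_lengthscales=3, n_periods=3)
        est.fit(X, coords)
        assert est.pvalues_.shape == (K,)
        assert est.statistics_.shape == (K, 17)
        assert est.adjusted_pvalues_.min() >= est.pvalues_.min()
        Xt = est.transform(X)
        assert Xt.shape == (N, int(est.get_support().sum()))

    def test_clone_and_params_round_trip(self):
        est = SMASH(n_lengthscales=4, combine="cauchy", alpha=0.01)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_grid_mid_lengthscale_used(self, rng):
        coords = rng.uniform(0, 1, (100, 2))
        specs = data_driven_grid(coords, 10, "gaussian", seed=0)
        assert len({s.parameter for s in specs}) == 10
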