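"""Tetrachorics, parallel analysis, EFA, reliability."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import mistkit as mk
from mistkit.classical import (
    BinaryDataMatrix,
    ClassicalError,
    alpha_if_deleted_prune,
    bvn_cdf,
    communalities_from_3pl,
    cronbach_alpha,
    efa,
    parallel_analysis,
    reliability_report,
    smooth_to_pd,
    tetrachoric_matrix,
    tetrachoric_pair,
    varimax,
)


class TestBVN:
    def test_against_scipy_mvn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h, k = rng.normal(size=2) * 2
            rho = rng.uniform(-0.95, 0.95)
            ref = multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]]
            ).cdf([h, k])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-10)

    def test_zero_thresholds(self):
        # P(X<0, Y<0) = 1/4 + asin(rho)/(2 pi)
        for rho in (-0.8, 0.0, 0.6):
            expect = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert float(bvn_cdf(0, 0, rho)) == pytest.approx(expect, abs=1e-9)


class TestTetrachoric:
    def test_null_columns_near_zero(self):
        rng = np.random.default_rng(1)
        x = (rng.random((5000, 6)) < 0.5).astype(int)
        corr = tetrachoric_matrix(BinaryDataMatrix(x))
        off = corr.values[np.triu_indices(6, k=1)]
        assert np.abs(off).max() < 0.05

    def test_recovers_latent_correlation(self):
        rng = np.random.default_rng(2)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10000)
        rho = tetrachoric_pair((z[:, 0] > 0).astype(int), (z[:, 1] > 0).astype(int))
        assert rho == pytest.approx(0.5, abs=0.05)

    def test_self_pair_saturates(self):
        rng = np.random.default_rng(3)
        x = (rng.random(800) < 0.5).astype(int)
        assert tetrachoric_pair(x, x) >= 0.99

    def test_antisymmetric_under_recoding(self):
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=4000)
        x = (z[:, 0] > 0).astype(int)
        y = (z[:, 1] > 0).astype(int)
        assert tetrachoric_pair(x, 1 - y) == pytest.approx(
            -tetrachoric_pair(x, y), abs=0.02
        )

    def test_constant_column_rejected(self):
        x = np.ones((100, 2), dtype=int)
        x[:, 1] = np.arange(100) % 2
        with pytest.raises(ClassicalError, match="degenerate-item"):
            tetrachoric_matrix(BinaryDataMatrix(x))

    def test_smoothing_produces_pd_unit_diagonal(self):
        bad = np.array([[1, 0.9, 0.1], [0.9, 1, 0.9], [0.1, 0.9, 1.0]])
        out, smoothed = smooth_to_pd(bad)
        assert smoothed
        assert np.linalg.eigvalsh(out).min() >= 1e-7
        assert np.allclose(np.diag(out), 1)


class TestParallelAnalysis:
    def test_retains_two_planted_factors(self, planted_2factor):
        _, data, _ = planted_2factor
        res = parallel_analysis(data, n_sim=100, seed=0)
        assert res.n_retained == 2

    def test_pure_noise_retains_none(self):
        spec = mk.PoolSpec(n_factors=2, items_per_factor=5,
                           loading_range=(0.0, 1e-4))
        _, data, _ = mk.simulate_item_pool(spec, mk.SimConfig(n=1000, seed=5))
        res = parallel_analysis(data, n_sim=60, seed=1)
        assert res.n_retained == 0

    def test_eigenvalue_trace_conservation(self, planted_2factor):
        _, data, _ = planted_2factor
        res = parallel_analysis(data, n_sim=10, seed=2)
        assert res.observed_eigenvalues.sum() == pytest.approx(data.p, abs=1e-6)
        assert res.n_sim == 10


class TestEFA:
    def test_block_structure_recovered(self):
        rng = np.random.default_rng(6)
        r = np.eye(10)
        r[:5, :5] = 0.5
        r[5:, 5:] = 0.5
        np.fill_diagonal(r, 1.0)
        sol = efa(None, k=2, corr=r)
        L = np.abs(sol.loadings)
        own = np.array([L[i].max() for i in range(10)])
        which = np.argmax(L, axis=1)
        assert np.all(own > 0.5)
        assert len(set(which[:5])) == 1 and len(set(which[5:])) == 1
        assert which[0] != which[5]
        cross = np.array([L[i].min() for i in range(10)])
        assert np.all(cross < 0.1)

    def test_rotation_leaves_communalities(self, planted_2factor):
        _, data, _ = planted_2factor
        r = tetrachoric_matrix(data)
        unrot = efa(None, k=2, rotation="none", corr=r)
        rot = efa(None, k=2, rotation="varimax", corr=r)
        assert np.allclose(unrot.communalities, rot.communalities, atol=1e-6)
        h2_from_rot = np.sum(rot.loadings**2, axis=1)
        assert np.allclose(h2_from_rot, rot.communalities, atol=1e-6)

    def test_varimax_matches_grid_search_oracle(self):
        L = np.array([[0.8, 0.2], [0.7, 0.3], [0.1, 0.75], [0.25, 0.6]])

        def criterion(Lr):
            v = Lr**2
            return np.sum(v.var(axis=0))

        best, best_angle = -np.inf, 0.0
        for ang in np.linspace(0, np.pi / 2, 200001):
            c, s = np.cos(ang), np.sin(ang)
            rot = L @ np.array([[c, -s], [s, c]])
            val = criterion(rot)
            if val > best:
                best, best_angle = val, ang
        ours = varimax(L, kaiser=False)
        assert criterion(ours) == pytest.approx(best, abs=1e-3)

    def test_uls_close_to_paf_on_clean_structure(self):
        r = np.eye(8)
        r[:4, :4] = 0.45
        r[4:, 4:] = 0.45
        np.fill_diagonal(r, 1.0)
        paf = efa(None, k=2, method="PAF", corr=r)
        uls = efa(None, k=2, method="ULS", corr=r)
        assert np.allclose(
            np.sort(np.abs(paf.loadings).max(axis=1)),
            np.sort(np.abs(uls.loadings).max(axis=1)),
            atol=0.05,
        )

    def test_residual_reconstruction_on_planted_data(self, planted_2factor):
        _, data, _ = planted_2factor
        r = tetrachoric_matrix(data).values
        sol = efa(None, k=2, corr=r)
        resid = r - sol.loadings @ sol.loadings.T
        np.fill_diagonal(resid, 0.0)
        rmsr = np.sqrt(np.mean(resid[np.triu_indices_from(resid, k=1)] ** 2))
        assert rmsr < 0.05


class TestCommunalitiesFrom3PL:
    def test_reference_point(self):
        params = mk.IRTParams(a=[1.702], b=[0.0], c=[0.5])
        assert communalities_from_3pl(params)[0] == pytest.approx(0.5)

    def test_limits_and_monotonicity(self):
        a = np.array([0.05, 0.5, 1.0, 2.0, 5.0, 50.0])
        h2 = communalities_from_3pl(mk.IRTParams(a=a, b=np.zeros(6), c=0.5))
        assert np.all(np.diff(h2) > 0)
        assert h2[0] < 0.01
        assert h2[-1] > 0.99


class TestAlpha:
    def test_hand_computed_three_item_example(self):
        x = np.array([
            [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1],
            [0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1],
        ], dtype=float)
        k = 3
        item_var = x.var(axis=0, ddof=1)
        total_var = x.sum(axis=1).var(ddof=1)
        by_hand = k / (k - 1) * (1 - item_var.sum() / total_var)
        assert cronbach_alpha(x) == pytest.approx(by_hand, abs=1e-12)

    def test_identical_columns_alpha_one(self):
        col = (np.arange(20) % 2)
        x = np.column_stack([col, col, col])
        assert cronbach_alpha(x) == pytest.approx(1.0)
        kept, trace = alpha_if_deleted_prune(BinaryDataMatrix(x.astype(int)))
        assert trace == []
        assert len(kept) == 3

    def test_planted_junk_removed_first(self):
        spec = mk.PoolSpec(n_factors=1, items_per_factor=10, n_junk=1,
                           loading_range=(0.6, 0.7))
        _, data, truth = mk.simulate_item_pool(spec, mk.SimConfig(n=800, seed=2))
        kept, trace = alpha_if_deleted_prune(data)
        assert trace[0]["removed"] == truth["junk_ids"][0]
        assert truth["junk_ids"][0] not in kept

    def test_pruning_never_lowers_alpha(self):
        rng = np.random.default_rng(8)
        x = (rng.random((300, 8)) < 0.5).astype(int)
        data = BinaryDataMatrix(x)
        kept, trace = alpha_if_deleted_prune(data)
        for step in trace:
            assert step["alpha_after"] > step["alpha_before"]


class TestReliabilityReport:
    @staticmethod
    def _bifactor_binary(n=3000, p=12, g=0.6, s=0.45, seed=7):
        rng = np.random.default_rng(seed)
        fac = np.repeat([0, 1], p // 2)
        G = rng.standard_normal(n)
        S = rng.standard_normal((n, 2))
        y = (g * G[:, None] + s * S[:, fac]
             + np.sqrt(1 - g**2 - s**2) * rng.standard_normal((n, p)))
        return BinaryDataMatrix((y > 0).astype(int)), fac, g, s

    def test_omega_g_matches_closed_form_oracle(self):
        data, fac, g, s = self._bifactor_binary()
        rep = reliability_report(data, fac, kind="tetrachoric")
        p = data.p
        g_load = np.full(p, g)
        r_true = np.outer(g_load, g_load) + np.full(p, s)[:, None] * np.full(p, s)[None, :] * (
            fac[:, None] == fac[None, :]
        )
        np.fill_diagonal(r_true, 1.0)
        closed_form = g_load.sum() ** 2 / r_true.sum()
        assert rep.omega_g == pytest.approx(closed_form, abs=0.05)
        assert 0 < rep.omega_F1 <= 1 and 0 < rep.omega_F2 <= 1
        assert rep.omega_F1 >= rep.omega_g * 0.5

    def test_single_common_factor_degenerate_bifactor(self):
        # no group factors: omega_g approaches the total-scale omega
        data, fac, g, _ = self._bifactor_binary(s=0.0, g=0.7, seed=9)
        rep = reliability_report(data, fac, kind="tetrachoric")
        p = data.p
        r_true = np.full((p, p), g * g)
        np.fill_diagonal(r_true, 1.0)
        omega_total = (p * g) ** 2 / r_true.sum()
        # a sample two-factor oblique fit on unidimensional data leaves a
        # little variance to pseudo-group factors, so the match is loose
        assert rep.omega_g == pytest.approx(omega_total, abs=0.10)
        assert rep.omega_g > 0.8

    def test_retest_identity_and_alignment(self):
        data, fac, *_ = self._bifactor_binary(n=400, seed=10)
        rep = reliability_report(data, fac, retest=data)
        assert rep.test_retest == pytest.approx(1.0)
        assert rep.alpha <= 1.0
        assert rep.iic_min <= rep.iic_max
        assert rep.itc_min <= rep.itc_max

    def test_variance_decomposition_shares_sum_to_one(self):
        data, fac, *_ = self._bifactor_binary(n=500, seed=11)
        rep = reliability_report(data, fac)
        vd = rep.variance_decomposition
        assert vd["share_F1"] + vd["share_F2"] == pytest.approx(1.0)
        assert 0 < vd["F1"] < 1 and 0 < vd["F2"] < 1
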