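"""Exploratory graph analysis: network, communities, loadings, bootstrap, fit."""

import numpy as np
import pytest

import mistkit as mk
from mistkit.ega import (
    EGAError,
    Network,
    Partition,
    boot_ega,
    detect_communities,
    ega,
    estimate_network,
    network_loadings,
    tefi,
    uva_redundancy,
    von_neumann_entropy,
)


def toy_network(weights, ids=None):
    w = np.asarray(weights, dtype=float)
    return Network(partial_correlations=w, n=500, lambda_selected=0.1,
                   ebic=0.0, gamma=0.5,
                   col_ids=ids or [f"item_{j}" for j in range(w.shape[0])])


def two_block_corr(p=10, rho=0.6):
    r = np.eye(p)
    half = p // 2
    r[:half, :half] = rho
    r[half:, half:] = rho
    np.fill_diagonal(r, 1.0)
    return r


class TestEstimateNetwork:
    def test_identity_matrix_gives_empty_network(self):
        net = estimate_network(np.eye(6), n=500)
        assert net.n_edges == 0
        assert np.all(net.partial_correlations == 0)

    def test_two_block_sparsity_pattern(self):
        net = estimate_network(two_block_corr(), n=1000)
        pc = net.partial_correlations
        assert np.abs(pc[:5, 5:]).max() < 1e-8
        within = np.abs(pc[:5, :5][np.triu_indices(5, k=1)])
        assert within.min() > 0.05

    def test_unpenalized_limit_matches_inverse(self):
        r = two_block_corr(6, 0.4)
        net = estimate_network(r, n=1000, lambdas=[0.0])
        inv = np.linalg.inv(r)
        d = np.sqrt(np.diag(inv))
        expect = -inv / np.outer(d, d)
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(net.partial_correlations, expect, atol=1e-6)

    def test_invariant_under_item_reordering(self):
        rng = np.random.default_rng(0)
        lam = np.full(8, 0.6)
        fac = np.repeat([0, 1], 4)
        x = lam * rng.standard_normal((800, 2))[:, fac] + 0.8 * rng.standard_normal((800, 8))
        r = np.corrcoef(x, rowvar=False)
        perm = rng.permutation(8)
        net1 = estimate_network(r, n=800)
        net2 = estimate_network(r[np.ix_(perm, perm)], n=800)
        # up to the coordinate-descent solver tolerance
        assert np.allclose(
            net2.partial_correlations,
            net1.partial_correlations[np.ix_(perm, perm)],
            atol=1e-3,
        )


class TestCommunities:
    def test_disconnected_cliques_recovered_exactly(self):
        w = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        w[i, j] = 0.4
        part = detect_communities(toy_network(w))
        labels = part.as_array([f"item_{j}" for j in range(8)])
        assert part.n_dims == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_planted_four_communities(self):
        rng = np.random.default_rng(1)
        p = 16
        w = rng.uniform(0.02, 0.05, (p, p))
        w = (w + w.T) / 2
        for c in range(4):
            idx = slice(4 * c, 4 * c + 4)
            w[idx, idx] = 0.4
        np.fill_diagonal(w, 0.0)
        part = detect_communities(toy_network(w))
        labels = part.as_array([f"item_{j}" for j in range(p)])
        assert part.n_dims == 4
        for c in range(4):
            assert len(set(labels[4 * c:4 * c + 4])) == 1

    def test_single_clique_is_one_community(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0.0)
        assert detect_communities(toy_network(w)).n_dims == 1

    def test_empty_network_rejected(self):
        with pytest.raises(EGAError, match="no-structure"):
            detect_communities(toy_network(np.zeros((4, 4))))


class TestNetworkLoadings:
    def test_toy_hand_computation(self):
        # A-B edge .5 inside dim 1; A-C edge .1 with C alone in dim 2
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        net = toy_network(w, ids=["A", "B", "C"])
        part = Partition({"A": 1, "B": 1, "C": 2})
        loads = network_loadings(net, part)
        # dim-1 within-strength = raw(A,1) + raw(B,1) = 1.0, so the dim-1
        # column is divided by sqrt(1) and the raw values survive; dim 2 is
        # a singleton with zero within-strength, so its column stays raw
        assert loads[0, 0] == pytest.approx(0.5)
        assert loads[0, 1] == pytest.approx(0.1)
        assert loads[2, 0] == pytest.approx(0.1)
        assert loads[1, 0] == pytest.approx(0.5)

    def test_isolated_node_zero_everywhere(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        net = toy_network(w)
        part = Partition({"item_0": 1, "item_1": 1, "item_2": 2})
        loads = network_loadings(net, part)
        assert np.all(loads[2] == 0)

    def test_label_permutation_permutes_columns(self):
        rng = np.random.default_rng(2)
        w = np.abs(rng.normal(0, 0.2, (6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = toy_network(w)
        p1 = Partition({f"item_{j}": 1 if j < 3 else 2 for j in range(6)})
        p2 = Partition({f"item_{j}": 2 if j < 3 else 1 for j in range(6)})
        l1 = network_loadings(net, p1)
        l2 = network_loadings(net, p2)
        assert np.allclose(l1, l2[:, ::-1])

    def test_qualitative_anchor_ordering(self):
        # factor loadings .40/.55/.70 map to increasing network loadings in
        # roughly the published low/moderate/high bands
        rng = np.random.default_rng(5)
        n = 2000
        lam = np.array([0.40, 0.55, 0.70] * 4)
        fac = np.repeat([0, 1], 6)
        x = lam * rng.standard_normal((n, 2))[:, fac] + np.sqrt(
            1 - lam**2
        ) * rng.standard_normal((n, 12))
        net = estimate_network(np.corrcoef(x, rowvar=False), n=n)
        part = detect_communities(net)
        loads = network_loadings(net, part)
        arr = part.as_array(net.col_ids)
        own = np.array([loads[i, arr[i] - 1] for i in range(12)])
        means = [own[lam == lv].mean() for lv in (0.40, 0.55, 0.70)]
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(0.15, abs=0.12)
        assert means[1] == pytest.approx(0.25, abs=0.12)
        assert means[2] == pytest.approx(0.35, abs=0.12)


class TestUVA:
    def test_wto_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        w = np.abs(rng.normal(0, 0.2, (4, 4)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        res = uva_redundancy(toy_network(w), threshold=2.0)
        a = np.abs(w)
        k = a.sum(axis=1)
        for i in range(4):
            for j in range(i + 1, 4):
                num = sum(a[i, u] * a[j, u] for u in range(4) if u not in (i, j))
                oracle = (num + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert res.wto[i, j] == pytest.approx(oracle, abs=1e-9)

    def test_duplicated_item_flagged(self):
        spec = mk.PoolSpec(n_factors=2, items_per_factor=6, n_redundant_pairs=1,
                           loading_range=(0.6, 0.75))
        _, data, truth = mk.simulate_item_pool(spec, mk.SimConfig(n=1000, seed=13))
        res = ega(data=data)
        uva = uva_redundancy(res.network, res.network_loadings, res.partition)
        flagged_pairs = {frozenset(f["pair"]) for f in uva.flagged_pairs}
        assert frozenset(truth["redundant_pairs"][0]) in flagged_pairs
        for f in uva.flagged_pairs:
            assert {"keep", "drop"} <= set(f)

    def test_independent_items_unflagged(self):
        net = estimate_network(np.eye(5) + 0.001, n=2000)
        res = uva_redundancy(net)
        assert res.flagged_pairs == []
        assert np.all((res.wto >= 0) & (res.wto <= 1))


class TestTEFI:
    def test_entropy_matches_direct_oracle(self):
        r = two_block_corr(4, 0.5)
        lam = np.linalg.eigvalsh(r / np.trace(r))
        oracle = -np.sum(lam * np.log(lam))
        assert von_neumann_entropy(r) == pytest.approx(oracle, abs=1e-9)

    def test_label_invariance(self):
        r = two_block_corr(8, 0.5)
        ids = [f"item_{j}" for j in range(8)]
        p1 = Partition({i: 1 if j < 4 else 2 for j, i in enumerate(ids)})
        p2 = Partition({i: 7 if j < 4 else 3 for j, i in enumerate(ids)})
        assert tefi(r, p1) == pytest.approx(tefi(r, p2), abs=1e-12)

    def test_true_partition_beats_merged(self):
        p = 16
        r = np.eye(p)
        for c in range(4):
            idx = slice(4 * c, 4 * c + 4)
            r[idx, idx] = 0.6
        np.fill_diagonal(r, 1.0)
        ids = [f"item_{j}" for j in range(p)]
        true = Partition({i: j // 4 + 1 for j, i in enumerate(ids)})
        merged = Partition({i: j // 8 + 1 for j, i in enumerate(ids)})
        assert tefi(r, true) < tefi(r, merged)


class TestPipeline:
    def test_planted_four_factor_recovery(self, planted_4factor):
        _, data, truth = planted_4factor
        res = ega(data=data)
        assert len(res.dims) == 4
        arr = res.partition.as_array(data.col_ids)
        for fac in range(4):
            members = arr[truth["factor_of"] == fac]
            assert len(set(members)) == 1

    def test_mist16_style_structure(self):
        # 5/5/3/3 dimension sizes, as in the 16-item graph-selected scale
        rng = np.random.default_rng(17)
        sizes = [5, 5, 3, 3]
        fac = np.repeat(range(4), sizes)
        n, p = 1500, 16
        lam = rng.uniform(0.6, 0.75, p)
        x = lam * rng.standard_normal((n, 4))[:, fac] + np.sqrt(
            1 - lam**2
        ) * rng.standard_normal((n, p))
        xb = (x > rng.uniform(-0.5, 0.5, p)).astype(int)
        res = ega(data=mk.BinaryDataMatrix(xb))
        assert len(res.dims) == 4
        arr = res.partition.as_array(res.network.col_ids)
        own = np.array([res.network_loadings[i, arr[i] - 1] for i in range(p)])
        assert np.mean(own >= 0.15) > 0.8

    def test_boot_ega_planted_structure(self, planted_4factor):
        _, data, _ = planted_4factor
        res = boot_ega(data, n_boot=30, seed=1)
        assert res.median_dims == 4
        assert min(res.item_stability.values()) >= 0.9
        assert min(res.structural_consistency.values()) >= 0.9
        assert sum(res.n_dims_distribution.values()) + res.n_failures == 30

    def test_boot_single_replicate_degenerate(self, planted_4factor):
        _, data, _ = planted_4factor
        res = boot_ega(data, n_boot=1, seed=2)
        assert len(res.n_dims_distribution) == 1
        assert set(res.item_stability.values()) <= {0.0, 1.0}

    def test_ambiguous_item_less_stable(self):
        rng = np.random.default_rng(23)
        n = 600
        fac = np.repeat([0, 1], 5)
        lam = np.full(10, 0.7)
        F = rng.standard_normal((n, 2))
        x = lam * F[:, fac] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 10))
        # one extra item loading equally on both factors
        amb = 0.45 * F[:, 0] + 0.45 * F[:, 1] + np.sqrt(
            1 - 2 * 0.45**2
        ) * rng.standard_normal(n)
        xb = (np.column_stack([x, amb]) > 0).astype(int)
        res = boot_ega(mk.BinaryDataMatrix(xb), n_boot=40, seed=3)
        amb_stab = res.item_stability["item_10"]
        clean = [v for k, v in res.item_stability.items() if k != "item_10"]
        assert amb_stab < min(clean)
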