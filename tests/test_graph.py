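"""Weighted graph metrics: closed forms, brute-force oracles, epoch
aggregation and the cross-band leave-one-out normalization."""

import numpy as np
import pandas as pd
import pytest

from rsnet import Band
from rsnet.connectivity import ConnectivityStack
from rsnet.graph import (aggregate_epochs, characteristic_path_length,
                         clustering_coefficient, metrics_from_stack,
                         normalize_metrics, small_world_index)


def brute_force_weighted_cc(w):
    """Triple-enumeration oracle for the geometric-mean clustering."""
    n = w.shape[0]
    wh = w / w.max()
    vals = []
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            vals.append(0.0)
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        vals.append(acc / (k * (k - 1)))
    return np.array(vals), float(np.mean(vals))


def brute_force_pl(w):
    """Exhaustive relaxation (Bellman-Ford style) all-pairs oracle."""
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(d, 0.0)
    for _ in range(n):  # n rounds guarantee convergence
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if d[i, k] + d[k, j] < d[i, j]:
                        d[i, j] = d[i, k] + d[k, j]
    off = d[~np.eye(n, dtype=bool)]
    return float(off[np.isfinite(off)].mean())


def random_weighted_graph(rng, n=12, density=0.6):
    w = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, 1)
    w = w + w.T
    return w


class TestClusteringCoefficient:
    def test_complete_graph_equal_weights(self):
        w = 0.7 * (1 - np.eye(6))
        per_node, global_cc = clustering_coefficient(w)
        assert np.allclose(per_node, 1.0)
        assert global_cc == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 0.9
        per_node, global_cc = clustering_coefficient(w)
        assert np.all(per_node == 0)
        assert global_cc == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng)
            per_node, global_cc = clustering_coefficient(w)
            bf_nodes, bf_global = brute_force_weighted_cc(w)
            assert np.abs(per_node - bf_nodes).max() < 1e-12
            assert abs(global_cc - bf_global) < 1e-12

    def test_negative_weight_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.1
        with pytest.raises(ValueError):
            clustering_coefficient(w)


class TestCharacteristicPathLength:
    def test_complete_graph_direct_edges(self):
        w = 0.5 * (1 - np.eye(5))
        assert characteristic_path_length(w) == pytest.approx(2.0)  # 1/0.5

    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert characteristic_path_length(w) == pytest.approx(4 / 3)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(10):
            w = random_weighted_graph(rng, n=10)
            assert abs(characteristic_path_length(w)
                       - brute_force_pl(w)) < 1e-12

    def test_isolated_node_warns_and_excludes(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        with pytest.warns(RuntimeWarning):
            pl = characteristic_path_length(w)
        assert np.isfinite(pl)


def stack_from_matrices(mats):
    mats = np.asarray(mats, dtype=float)
    return ConnectivityStack(
        data=mats[None], bands=[Band("theta", 4, 8)],
        channel_names=[f"c{i}" for i in range(mats.shape[-1])],
        provenance={"subject_id": "S01", "condition": "PRE"})


class TestAggregateEpochs:
    def test_identical_matrices_equal_single(self, rng):
        w = random_weighted_graph(rng, n=6)
        stack = stack_from_matrices([w, w, w])
        agg = aggregate_epochs(stack, "cc")
        assert agg["theta"] == pytest.approx(clustering_coefficient(w)[1])

    def test_mean_contract_and_order_invariance(self, rng):
        w1, w2 = (random_weighted_graph(rng, n=6) for _ in range(2))
        cc1 = clustering_coefficient(w1)[1]
        cc2 = clustering_coefficient(w2)[1]
        a = aggregate_epochs(stack_from_matrices([w1, w2]), "cc")["theta"]
        b = aggregate_epochs(stack_from_matrices([w2, w1]), "cc")["theta"]
        assert a == pytest.approx((cc1 + cc2) / 2)
        assert a == b

    def test_mean_matrix_mode_and_swi(self, rng):
        w1, w2 = (random_weighted_graph(rng, n=6) for _ in range(2))
        stack = stack_from_matrices([w1, w2])
        mm = aggregate_epochs(stack, "swi", mode="mean-matrix")["theta"]
        assert mm == pytest.approx(small_world_index((w1 + w2) / 2))
        with pytest.raises(ValueError):
            aggregate_epochs(stack, "modularity")


def toy_table(values, conditions, bands, subject="S01", metric="cc"):
    rows = []
    i = 0
    for c in conditions:
        for b in bands:
            rows.append({"subject": subject, "condition": c, "band": b,
                         "cc_raw": values[i], "pl_raw": values[i]})
            i += 1
    return pd.DataFrame(rows)


class TestNormalizeMetrics:
    def test_two_cell_toy(self):
        t = toy_table([2.0, 4.0], ["A", "B"], ["theta"])
        out = normalize_metrics(t).set_index("condition")
        assert out.loc["A", "cc_norm"] == pytest.approx(0.5)
        assert out.loc["B", "cc_norm"] == pytest.approx(2.0)

    def test_constant_grid_fixed_point(self):
        t = toy_table([3.0] * 6, ["A", "B"], ["t", "a1", "a2"])
        out = normalize_metrics(t)
        assert np.allclose(out["cc_norm"], 1.0)
        assert np.allclose(out["swi"], 1.0)

    def test_matches_leave_one_out_loop(self, rng):
        conditions = [f"C{i}" for i in range(6)]
        bands = ["t", "a1", "a2"]
        vals = rng.uniform(0.5, 2.0, 18)
        out = normalize_metrics(toy_table(vals, conditions, bands))
        for idx in range(18):
            others = np.delete(vals, idx)
            assert abs(out["cc_norm"][idx] - vals[idx] / others.mean()) < 1e-12

    def test_closed_form_identity(self, rng):
        # normalized = raw * (n-1) / (sum - raw), cellwise
        vals = rng.uniform(0.5, 2.0, 12)
        out = normalize_metrics(
            toy_table(vals, [f"C{i}" for i in range(6)], ["t", "a"]))
        n = vals.size
        expected = vals * (n - 1) / (vals.sum() - vals)
        assert np.abs(out["cc_norm"].to_numpy() - expected).max() < 1e-12

    def test_scale_robustness(self, rng):
        vals = rng.uniform(0.5, 2.0, 12)
        t1 = toy_table(vals, [f"C{i}" for i in range(6)], ["t", "a"])
        t2 = t1.copy()
        t2[["cc_raw", "pl_raw"]] *= 7.3
        a, b = normalize_metrics(t1), normalize_metrics(t2)
        for col in ("cc_norm", "pl_norm", "swi"):
            assert np.allclose(a[col], b[col])

    def test_bands_scope_normalizes_within_condition(self):
        t = toy_table([2.0, 4.0, 1.0, 1.0], ["A", "B"], ["t", "a"])
        out = normalize_metrics(t, scope="bands").set_index(
            ["condition", "band"])
        # within condition A: 2 vs 4 -> 0.5 and 2.0
        assert out.loc[("A", "t"), "cc_norm"] == pytest.approx(0.5)
        assert out.loc[("A", "a"), "cc_norm"] == pytest.approx(2.0)
        assert out.loc[("B", "t"), "cc_norm"] == pytest.approx(1.0)

    def test_missing_cell_raises_with_names(self):
        t = toy_table([2.0, 4.0, 1.0, 5.0], ["A", "B"], ["t", "a"]).iloc[:3]
        with pytest.raises(ValueError, match="missing cells"):
            normalize_metrics(t)

    def test_metrics_from_stack_roundtrip(self, rng):
        mats = [random_weighted_graph(rng, n=6) for _ in range(3)]
        t = metrics_from_stack(stack_from_matrices(mats))
        assert list(t.columns) == ["subject", "condition", "band",
                                   "cc_raw", "pl_raw"]
        assert t.loc[0, "cc_raw"] == pytest.approx(np.mean(
            [clustering_coefficient(m)[1] for m in mats]))
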