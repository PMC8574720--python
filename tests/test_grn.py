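import numpy as np
import pandas as pd
import pytest

from mra.grn import (
    BoostingParams,
    WeightedNetwork,
    apply_dpi,
    equal_frequency_bins,
    filter_regulons,
    infer_grn_boosting,
    miller_madow_mi_bits,
    pairwise_mutual_information,
    plugin_mi_bits,
    sign_regulons,
    _joint_counts,
)
from mra.io import ExpressionMatrix, MraError
from mra.simulate import SimulationConfig, simulate_expression, simulate_network


def _matrix(rows: dict, samples=None) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float))


class TestBoosting:
    def test_noise_free_regulator_is_unique_top_edge(self):
        rng = np.random.default_rng(0)
        n = 60
        trs = [f"TR{i:02d}" for i in range(51)]
        rows = {t: rng.standard_normal(n) for t in trs}
        rows["G1"] = rows["TR03"].copy()  # exact copy of one regulator
        m = _matrix(rows)
        net = infer_grn_boosting(m, trs, BoostingParams(seed=1))
        g1 = net.edges[net.edges["target"] == "G1"]
        assert list(g1["regulator"]) == ["TR03"]
        assert g1["weight"].iloc[0] == pytest.approx(1.0)

    def test_pure_noise_target_rarely_keeps_edges(self):
        rng = np.random.default_rng(1)
        n, reps = 50, 100
        trs = [f"TR{i:02d}" for i in range(20)]
        empty = 0
        base = {t: rng.standard_normal(n) for t in trs}
        for r in range(reps):
            rows = dict(base)
            rows["G1"] = rng.standard_normal(n)
            m = _matrix(rows)
            net = infer_grn_boosting(m, trs, BoostingParams(n_rounds=100, seed=r))
            empty += int((net.edges["target"] == "G1").sum() == 0)
        assert empty >= 90

    def test_determinism_and_sample_order_invariance(self):
        cfg = SimulationConfig(
            n_tr=5, n_targets=30, n_samples_per_group=15, regulon_size_range=(5, 8), seed=2
        )
        net = simulate_network(cfg)
        expr, _, _ = simulate_expression(net, cfg)
        p = BoostingParams(n_rounds=50, seed=3)
        a = infer_grn_boosting(expr, net.tr_ids, p).edges
        b = infer_grn_boosting(expr, net.tr_ids, p).edges
        pd.testing.assert_frame_equal(a, b)
        shuffled = ExpressionMatrix(expr.data[list(expr.data.columns[::-1])])
        c = infer_grn_boosting(shuffled, net.tr_ids, p).edges
        pd.testing.assert_frame_equal(a, c)

    def test_too_few_regulators_rejected(self):
        m = _matrix({"TR1": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                     "G1": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]})
        with pytest.raises(MraError):
            infer_grn_boosting(m, ["TR1"], BoostingParams(seed=1))


class TestMutualInformation:
    def test_perfect_dependence_three_bins(self):
        x = np.arange(9.0)
        b = equal_frequency_bins(x, 3)
        assert plugin_mi_bits(_joint_counts(b, b, 3, 3)) == pytest.approx(np.log2(3))

    def test_diagonal_counts_give_one_bit(self):
        assert plugin_mi_bits(np.array([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_miller_madow_adds_bias_term(self):
        counts = np.array([[5, 0], [0, 5]])
        expected = 1.0 + (2 + 2 - 2 - 1) / (2 * 10 * np.log(2))
        assert miller_madow_mi_bits(counts) == pytest.approx(expected)

    def test_independent_pairs_kept_near_alpha_rate(self):
        rng = np.random.default_rng(4)
        n, n_pairs = 500, 200
        rows = {"TR01": rng.standard_normal(n)}
        for i in range(n_pairs):
            rows[f"G{i:03d}"] = rng.standard_normal(n)
        m = _matrix(rows)
        net = pairwise_mutual_information(m, ["TR01"], seed=5)
        rate = len(net.edges) / n_pairs
        assert 0.005 <= rate <= 0.12  # ~alpha = 0.05

    def test_constant_row_dropped(self):
        rng = np.random.default_rng(6)
        rows = {"TR01": rng.standard_normal(20), "G1": np.ones(20),
                "G2": rng.standard_normal(20)}
        net = pairwise_mutual_information(_matrix(rows), ["TR01"], seed=7)
        assert "G1" not in set(net.edges["target"])


class TestDpi:
    def test_strictly_weakest_edge_removed_at_zero_tolerance(self):
        e = pd.DataFrame({"regulator": ["A", "B", "A"], "target": ["B", "C", "C"],
                          "weight": [0.9, 0.8, 0.3]})
        out = apply_dpi(WeightedNetwork(e, "MI"), tolerance=0.0)
        assert out.edges["weight"].tolist() == [0.9, 0.8]

    def test_tolerance_protects_borderline_edge(self):
        e = pd.DataFrame({"regulator": ["A", "B", "A"], "target": ["B", "C", "C"],
                          "weight": [0.9, 0.8, 0.75]})
        out = apply_dpi(WeightedNetwork(e, "MI"), tolerance=0.15)
        assert len(out.edges) == 3  # threshold 0.68 < 0.75

    def test_rejects_non_mi_networks(self):
        e = pd.DataFrame({"regulator": ["A"], "target": ["B"], "weight": [1.0]})
        with pytest.raises(MraError):
            apply_dpi(WeightedNetwork(e, "BOOSTING"))


class TestFilterRegulons:
    @pytest.mark.parametrize("size,kept", [(9, 0), (10, 10)])
    def test_minimum_regulon_size_boundary(self, size, kept):
        e = pd.DataFrame({"regulator": ["TR1"] * size,
                          "target": [f"G{i}" for i in range(size)],
                          "weight": [0.5] * size})
        out = filter_regulons(WeightedNetwork(e, "MI"), min_size=10)
        assert len(out.edges) == kept

    def test_empty_and_idempotent(self):
        empty = WeightedNetwork(pd.DataFrame(columns=["regulator", "target", "weight"]), "MI")
        assert len(filter_regulons(empty).edges) == 0
        e = pd.DataFrame({"regulator": ["TR1"] * 12,
                          "target": [f"G{i}" for i in range(12)],
                          "weight": [0.5] * 12})
        once = filter_regulons(WeightedNetwork(e, "MI"))
        twice = filter_regulons(once)
        pd.testing.assert_frame_equal(once.edges, twice.edges)


class TestSignRegulons:
    def _net(self, targets):
        e = pd.DataFrame({"regulator": ["TR1"] * len(targets), "target": targets,
                          "weight": np.linspace(0.5, 1.0, len(targets))})
        return WeightedNetwork(e, "MI")

    def test_identical_and_negated_rows(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        rows = {"TR1": x}
        targets = []
        for i in range(5):
            rows[f"P{i}"] = x + rng.normal(0, 1e-6, 30)
            rows[f"N{i}"] = -x + rng.normal(0, 1e-6, 30)
            targets += [f"P{i}", f"N{i}"]
        m = _matrix(rows)
        regs = sign_regulons(self._net(targets), m, min_regulon_size=10)
        assert len(regs) == 1
        modes = dict(zip(regs[0].targets, regs[0].modes))
        assert all(modes[f"P{i}"] == 1 and modes[f"N{i}"] == -1 for i in range(5))

    def test_planted_mode_recovery_on_simulation(self):
        cfg = SimulationConfig(
            n_tr=10, n_targets=120, n_samples_per_group=50,
            regulon_size_range=(10, 12), fraction_differential=0.0,
            noise_sd=0.25, seed=9,
        )
        net = simulate_network(cfg)
        expr, _, _ = simulate_expression(net, cfg)
        edges = net.edges()[["regulator", "target", "weight"]]
        regs = sign_regulons(WeightedNetwork(edges, "MI"), expr, min_regulon_size=5)
        true_modes = {(r, t): m for r, tl in net.regulons.items() for t, m, _ in tl}
        ok = tot = 0
        for reg in regs:
            for t, mode in zip(reg.targets, reg.modes):
                tot += 1
                ok += int(mode == true_modes[(reg.tr_id, t)])
        assert tot > 0 and ok / tot >= 0.95
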