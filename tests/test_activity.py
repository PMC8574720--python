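import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from mra.activity import (
    FOLD_CHANGE,
    SignatureVector,
    activity_matrix,
    area_nes,
    fgsea_scores,
    fold_change_signature,
    gsea_es,
    gsva_scores,
    gsva_set_score,
    meandiff_activity,
    rank_to_normal,
    single_sample_signature,
    _es_from_positions,
    _kernel_cdf_scores,
    _ranked,
)
from mra.grn import SignedRegulon
from mra.io import HIGH, LOW, ExpressionMatrix, MraError, PhenotypeLabels

from conftest import regulons_from_truth


def _reg(targets, modes, conf=None):
    conf = np.ones(len(targets)) if conf is None else np.asarray(conf, dtype=float)
    return SignedRegulon("t", list(targets), np.asarray(modes, dtype=int), conf)


class TestSingleSampleSignature:
    def test_constant_gene_excluded_and_mean_sample_is_zero(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 5.0], "s2": [2.0, 2.0, 7.0], "s3": [3.0, 2.0, 9.0]},
            index=["a", "const", "b"],
        )
        sig = single_sample_signature(ExpressionMatrix(df), "s2")
        assert "const" not in sig.values.index
        assert np.allclose(sig.values.to_numpy(), 0.0)  # s2 is the mean profile

    def test_normal_quantile_mapping_for_three_genes(self):
        sig = SignatureVector(pd.Series({"a": 5.0, "b": 1.0, "c": 3.0}))
        mapped = rank_to_normal(sig).values
        assert mapped["b"] == pytest.approx(norm.ppf(0.25))
        assert mapped["c"] == pytest.approx(0.0)
        assert mapped["a"] == pytest.approx(norm.ppf(0.75))


class TestMeanDiff:
    def test_worked_example(self):
        reg = _reg(["a", "b", "c"], [1, 1, -1])
        sig = SignatureVector(pd.Series({"a": 1.0, "b": 0.6, "c": -0.8}))
        assert meandiff_activity(reg, sig) == pytest.approx(1.6)

    def test_missing_mode_group_contributes_zero(self):
        reg = _reg(["a", "b"], [1, 1])
        sig = SignatureVector(pd.Series({"a": 0.5, "b": -0.5}))
        assert meandiff_activity(reg, sig) == pytest.approx(0.0)

    def test_no_targets_present_is_error(self):
        reg = _reg(["x"], [1])
        with pytest.raises(MraError):
            meandiff_activity(reg, SignatureVector(pd.Series({"a": 1.0})))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mode_flip_negates_score(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(10)]
        reg = _reg(genes[:6], rng.choice([-1, 1], 6))
        sig = SignatureVector(pd.Series(rng.standard_normal(10), index=genes))
        assert meandiff_activity(reg.flipped(), sig) == pytest.approx(
            -meandiff_activity(reg, sig)
        )


class TestAreaNes:
    def test_single_target_identity(self):
        reg = _reg(["a"], [1])
        assert area_nes(reg, SignatureVector(pd.Series({"a": 1.645}))) == pytest.approx(1.645)

    def test_equal_weights_cancel(self):
        reg = _reg(["a", "b"], [1, 1])
        sig = SignatureVector(pd.Series({"a": 1.0, "b": -1.0}))
        assert area_nes(reg, sig) == pytest.approx(0.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mode_flip_negates_nes(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(12)]
        reg = _reg(genes[:5], rng.choice([-1, 1], 5), rng.uniform(0.2, 1.0, 5))
        sig = SignatureVector(pd.Series(rng.standard_normal(12), index=genes))
        assert area_nes(reg.flipped(), sig) == pytest.approx(-area_nes(reg, sig))


class TestGsva:
    def _m(self, n_genes=6, n_samples=8, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((n_genes, n_samples)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(n_samples)],
            )
        )

    def test_full_set_scores_one(self):
        m = self._m()
        reg = _reg([f"g{i}" for i in range(6)], [1] * 6)
        assert np.allclose(gsva_scores(m, [reg]).to_numpy(), 1.0)

    def test_mode_swap_negates_regulon_score(self):
        m = self._m(seed=1)
        reg = _reg(["g0", "g2", "g4"], [1, 1, -1])
        a = gsva_scores(m, [reg])
        b = gsva_scores(m, [reg.flipped()])
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_matches_exhaustive_walk_on_four_genes(self):
        m = self._m(n_genes=4, n_samples=5, seed=2)
        reg = _reg(["g1", "g3"], [1, 1])
        got = gsva_scores(m, [reg])
        f = _kernel_cdf_scores(m)
        genes = list(m.data.index)
        for j, s in enumerate(m.sample_ids):
            col = f[s]
            order = sorted(range(4), key=lambda i: (-col.iloc[i], genes[i]))
            ranks = {genes[i]: order.index(i) + 1 for i in range(4)}
            r = np.array([abs(2.0 - ranks[g]) for g in sorted(genes, key=lambda g: ranks[g])])
            hits = np.array([g in {"g1", "g3"} for g in sorted(genes, key=lambda g: ranks[g])])
            assert got.iloc[0, j] == pytest.approx(gsva_set_score(r, hits))


class TestFoldChange:
    def _labels(self, samples):
        half = len(samples) // 2
        return PhenotypeLabels(
            pd.Series([HIGH] * half + [LOW] * (len(samples) - half), index=samples)
        )

    def test_group_difference(self):
        df = pd.DataFrame([[2.0, 4.0, 1.0, 1.0]], index=["g"], columns=list("abcd"))
        m = ExpressionMatrix(df)
        sig = fold_change_signature(m, self._labels(list("abcd")))
        assert sig.values["g"] == pytest.approx(2.0)
        assert sig.kind == FOLD_CHANGE

    def test_label_swap_negates(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((5, 6)),
                          index=[f"g{i}" for i in range(5)], columns=list("abcdef"))
        m = ExpressionMatrix(df)
        lab = self._labels(list("abcdef"))
        swapped = PhenotypeLabels(lab.labels.map({HIGH: LOW, LOW: HIGH}))
        a = fold_change_signature(m, lab).values
        b = fold_change_signature(m, swapped).values
        assert np.allclose(a.to_numpy(), -b.to_numpy())

    def test_missing_class_is_error(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        lab = PhenotypeLabels(pd.Series([HIGH, HIGH], index=["a", "b"]))
        with pytest.raises(MraError):
            fold_change_signature(ExpressionMatrix(df), lab)


class TestGseaEs:
    SIG = SignatureVector(
        pd.Series({"g1": 3.0, "g2": 2.0, "g3": 1.0, "g4": -1.0, "g5": -2.0}), FOLD_CHANGE
    )

    def test_weighted_walk_top_pair(self):
        assert gsea_es(self.SIG, {"g1", "g2"}, 1.0) == pytest.approx(1.0)

    def test_unweighted_walk_bottom_gene(self):
        assert gsea_es(self.SIG, {"g5"}, 0.0) == pytest.approx(-1.0)

    def test_full_set(self):
        assert gsea_es(self.SIG, {"g1", "g2", "g3", "g4", "g5"}) == pytest.approx(1.0)

    def test_matches_position_formula_exhaustively(self):
        rng = np.random.default_rng(4)
        sig = pd.Series(rng.standard_normal(10), index=[f"g{i}" for i in range(10)])
        vals, genes = _ranked(sig)
        absw = np.abs(vals)
        sv = SignatureVector(sig, FOLD_CHANGE)
        for k in (1, 2, 3):
            for comb in itertools.combinations(range(10), k):
                es_fast = _es_from_positions(absw, np.array([comb]))[0]
                es_walk = gsea_es(sv, {genes[i] for i in comb})
                assert es_fast == pytest.approx(es_walk, abs=1e-12)


class TestFgsea:
    def test_constant_signature_gives_null_result(self):
        sig = SignatureVector(pd.Series(0.0, index=[f"g{i}" for i in range(8)]), FOLD_CHANGE)
        reg = _reg(["g0", "g1"], [1, 1])
        res = fgsea_scores(sig, [reg], n_perm=50, seed=5)
        assert res.loc["t", "es"] == 0.0
        assert res.loc["t", "p"] == pytest.approx(1.0)

    def test_es_independent_of_null_size(self):
        rng = np.random.default_rng(6)
        sig = SignatureVector(
            pd.Series(rng.standard_normal(20), index=[f"g{i}" for i in range(20)]), FOLD_CHANGE
        )
        reg = _reg(["g0", "g3", "g7"], [1, -1, 1])
        a = fgsea_scores(sig, [reg], n_perm=100, seed=7)
        b = fgsea_scores(sig, [reg], n_perm=200, seed=7)
        assert a.loc["t", "es"] == b.loc["t", "es"]

    def test_label_null_observed_es_matches_gene_null_observed_es(self, small_cohort):
        from mra.activity import fgsea_label_scores

        _, net, expr, labels, _ = small_cohort
        regs = regulons_from_truth(net)[:5]
        fc = fold_change_signature(expr, labels)
        a = fgsea_scores(fc, regs, n_perm=50, seed=1)
        b = fgsea_label_scores(expr, labels, regs, n_perm=50, seed=1)
        assert np.allclose(a["es"], b["es"])

    def test_label_null_p_uniform_under_exchangeable_groups(self):
        from scipy.stats import kstest

        from mra.activity import fgsea_label_scores

        rng = np.random.default_rng(10)
        ps = []
        genes = [f"g{j}" for j in range(60)]
        samples = [f"s{j}" for j in range(20)]
        lab = PhenotypeLabels(pd.Series([HIGH] * 10 + [LOW] * 10, index=samples))
        reg = _reg(genes[:8], [1] * 8)
        for i in range(200):
            # correlated block: the regulon targets share a latent factor
            latent = rng.standard_normal(20)
            x = rng.standard_normal((60, 20))
            x[:8] += latent
            m = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
            ps.append(fgsea_label_scores(m, lab, [reg], n_perm=100, seed=i).loc["t", "p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_permutation_p_uniform_under_null(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        ps = []
        for i in range(500):
            sig = SignatureVector(
                pd.Series(rng.standard_normal(50), index=[f"g{j}" for j in range(50)]),
                FOLD_CHANGE,
            )
            reg = _reg([f"g{j}" for j in range(8)], [1] * 8)
            ps.append(fgsea_scores(sig, [reg], n_perm=200, seed=i).loc["t", "p"])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestEngineSignAgreement:
    def test_planted_high_trs_more_active_in_high_samples(self, small_cohort):
        cfg, net, expr, labels, _ = small_cohort
        regs = regulons_from_truth(net)
        h, low = labels.high_samples, labels.low_samples
        diff_trs = list(net.differential)
        assert diff_trs
        for engine in ("MEANDIFF", "AREA", "GSVA"):
            act = activity_matrix(expr, regs, engine)
            ok = 0
            for tr in diff_trs:
                delta, direction = net.differential[tr]
                gap = act.loc[tr, h].mean() - act.loc[tr, low].mean()
                ok += int((gap > 0) == (direction == HIGH))
            assert ok / len(diff_trs) >= 0.95, engine
        fc = fold_change_signature(expr, labels)
        res = fgsea_scores(fc, regs, n_perm=200, seed=9)
        ok = 0
        for tr in diff_trs:
            _, direction = net.differential[tr]
            ok += int((res.loc[tr, "es"] > 0) == (direction == HIGH))
        assert ok / len(diff_trs) >= 0.95
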