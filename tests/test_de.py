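import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from eeseq import (DEConfig, DifferentialExpression, ExpressionMatrix,
                   SampleTable, SimConfig, call_de, cpm, fold_changes,
                   gene_test, simulate_experiment, tmm_factors)
from conftest import brute_force_tmm


def _matrix(arr, cols=None):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"g{i:03d}" for i in range(arr.shape[0])],
                     columns=cols), "counts")


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = np.array([10.0, 200.0, 3000.0, 40.0, 7.0])
        mat = _matrix(np.column_stack([col, col, col]))
        assert (tmm_factors(mat) == 1.0).all()

    def test_depth_only_difference_absorbed(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, size=300).astype(float) + 1
        mat = _matrix(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(mat), 1.0, atol=1e-12)

    def test_log_mean_is_zero(self, toy_counts):
        f = tmm_factors(toy_counts)
        assert abs(np.log(f).mean()) < 1e-12
        assert (f > 0).all()

    def test_matches_brute_force_oracle(self, toy_counts):
        f = tmm_factors(toy_counts)
        # recover the reference the implementation picked (factor exactly 1
        # before centring corresponds to argmin of the q75 criterion)
        x = toy_counts.values.to_numpy()
        q75 = np.quantile(x / x.sum(axis=0), 0.75, axis=0)
        ref = toy_counts.sample_ids[int(np.argmin(np.abs(q75 - q75.mean())))]
        oracle = brute_force_tmm(toy_counts.values, ref)
        np.testing.assert_allclose(f[oracle.index], oracle, atol=1e-10)

    def test_relabelling_invariance(self, toy_counts):
        f = tmm_factors(toy_counts)
        shuffled = toy_counts.subset_samples(["C", "A", "E", "B", "D"])
        g = tmm_factors(shuffled)
        np.testing.assert_allclose(f[g.index], g, atol=1e-12)

    def test_all_zero_sample_errors(self):
        mat = _matrix([[1.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(mat)


class TestCPM:
    def test_identity_factors_sum_to_million(self, toy_counts):
        out = cpm(toy_counts)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6)
        assert out.unit == "CPM"

    def test_doubling_a_library_leaves_cpm_unchanged(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(50, 100).astype(float) + 1
        b = rng.poisson(50, 100).astype(float) + 1
        base = cpm(_matrix(np.column_stack([a, b])))
        doubled = cpm(_matrix(np.column_stack([2 * a, b])))
        np.testing.assert_allclose(base.values.to_numpy(),
                                   doubled.values.to_numpy())

    def test_hand_computed_toy(self):
        mat = _matrix([[10.0, 30.0], [90.0, 70.0]])
        factors = pd.Series([2.0, 0.5], index=["s0", "s1"])
        out = cpm(mat, factors)
        # libsizes 100 -> effective 200 and 50
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[50000.0, 600000.0],
                                    [450000.0, 1400000.0]])


class TestFoldChanges:
    def test_identical_groups_zero(self, toy_counts):
        c = cpm(toy_counts)
        lfc = fold_changes(c, ["A", "B"], ["A", "B"])
        np.testing.assert_allclose(lfc, 0.0)

    def test_doubled_mean_gives_one(self):
        c = ExpressionMatrix(pd.DataFrame({"a": [40.0], "b": [20.0]},
                                          index=["g"]), "CPM")
        assert fold_changes(c, ["a"], ["b"], prior_count=0.0)["g"] == 1.0

    def test_prior_damping_at_zero(self):
        c = ExpressionMatrix(pd.DataFrame({"a": [3.0], "b": [0.0]},
                                          index=["g"]), "CPM")
        lfc = fold_changes(c, ["a"], ["b"], prior_count=0.5)
        assert lfc["g"] == pytest.approx(np.log2(3.5 / 0.5))

    def test_empty_group_errors(self, toy_counts):
        with pytest.raises(ValueError, match="nonempty"):
            fold_changes(cpm(toy_counts), [], ["A"])


def _two_groups(n=6):
    ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    df = pd.DataFrame(
        {"litter": "L1", "treatment": ["EE"] * n + ["B"] * n,
         "timepoint": "1h", "sex": "M"},
        index=pd.Index(ids, name="sample_id"))
    return SampleTable(df), ids[:n], ids[n:]


class TestGeneTest:
    def test_degenerate_zero_variance_is_null(self):
        mat = _matrix(np.full((3, 4), 100.0), cols=["a0", "a1", "b0", "b1"])
        p = gene_test(mat, ["a0", "a1"], ["b0", "b1"], DEConfig())
        assert not p.isna().any()
        np.testing.assert_allclose(p, 1.0)

    def test_small_group_recommends_alternative(self):
        mat = _matrix(np.ones((3, 3)) * 50, cols=["a0", "b0", "b1"])
        with pytest.raises(ValueError, match="nb_exact_mom"):
            gene_test(mat, ["a0"], ["b0", "b1"], DEConfig())

    def test_null_calibration(self):
        # no-effect NB simulation: the Welch log-CPM test should reject at
        # close to nominal rate; 10 seeds, at least 8 within [0.03, 0.07]
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            mu = rng.uniform(50, 2000, size=2000)
            phi = 0.05
            counts = rng.negative_binomial(
                1 / phi, 1 / (1 + phi * mu[:, None]), size=(2000, 12))
            mat = _matrix(counts.astype(float))
            cols = mat.sample_ids
            p = gene_test(mat, cols[:6], cols[6:], DEConfig())
            frac = float((p < 0.05).mean())
            ok += 0.03 <= frac <= 0.07
        assert ok >= 8

    def test_power_on_strong_effect(self):
        # 4-fold induction of 50 genes at low dispersion is detected at
        # p < 0.02 for at least 90% of the affected genes
        rng = np.random.default_rng(7)
        phi = 0.01
        mu = np.tile(rng.uniform(100, 1000, size=500)[:, None], (1, 12))
        affected = np.arange(50)
        mu[affected, :6] *= 4
        counts = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu))
        mat = _matrix(counts.astype(float))
        cols = mat.sample_ids
        p = gene_test(mat, cols[:6], cols[6:], DEConfig())
        assert (p.iloc[affected] < 0.02).mean() >= 0.90

    def test_nb_exact_mom_basics(self):
        rng = np.random.default_rng(9)
        mu = np.tile(rng.uniform(50, 500, size=50)[:, None], (1, 6))
        mu[0, :3] *= 6  # strong effect on gene 0
        counts = rng.poisson(mu).astype(float)
        mat = _matrix(counts)
        cols = mat.sample_ids
        p = gene_test(mat, cols[:3], cols[3:], DEConfig(test="nb_exact_mom"))
        assert ((p >= 0) & (p <= 1)).all()
        assert p.iloc[0] < 0.02
        assert p.iloc[1:].median() > 0.1

    def test_nb_exact_mom_allows_single_sample_groups(self):
        mat = _matrix([[500.0, 30.0], [40.0, 35.0], [60.0, 55.0]],
                      cols=["a", "b"])
        p = gene_test(mat, ["a"], ["b"], DEConfig(test="nb_exact_mom"))
        assert ((p >= 0) & (p <= 1)).all()


class TestCallDE:
    def test_threshold_examples(self):
        lfc = pd.Series([0.30, 0.30, -0.30, 0.1],
                        index=["g1", "g2", "g3", "g4"])
        p = pd.Series([0.01, 0.05, 0.01, 0.001],
                      index=["g1", "g2", "g3", "g4"])
        table, summary = call_de(lfc, p, DEConfig())
        assert table.loc["g1", "call"] == "up"       # both thresholds pass
        assert table.loc["g2", "call"] == "none"     # p fails
        assert table.loc["g3", "call"] == "down"
        assert table.loc["g4", "call"] == "none"     # fold change fails
        assert summary == {"n_up": 1, "n_down": 1}

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        idx = [f"g{i}" for i in range(n)]
        lfc = pd.Series(rng.normal(0, 0.5, n), index=idx)
        p = pd.Series(rng.uniform(0, 0.1, n), index=idx)
        cfg = DEConfig()
        table, _ = call_de(lfc, p, cfg)
        cut = np.log2(cfg.fc_threshold)
        for g in idx:
            if p[g] < cfg.p_threshold and lfc[g] >= cut:
                assert table.loc[g, "call"] == "up"
            elif p[g] < cfg.p_threshold and lfc[g] <= -cut:
                assert table.loc[g, "call"] == "down"
            else:
                assert table.loc[g, "call"] == "none"

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(500)]
        lfc = pd.Series(rng.normal(0, 0.6, 500), index=idx)
        p = pd.Series(rng.uniform(0, 0.05, 500), index=idx)
        base = call_de(lfc, p, DEConfig())[1]
        tighter_fc = call_de(lfc, p, DEConfig(fc_threshold=1.5))[1]
        tighter_p = call_de(lfc, p, DEConfig(p_threshold=0.005))[1]
        for tight in (tighter_fc, tighter_p):
            assert tight["n_up"] <= base["n_up"]
            assert tight["n_down"] <= base["n_down"]


class TestModelInterface:
    def test_group_swap_negates_and_mirrors(self):
        out = simulate_experiment(SimConfig(n_genes=400, seed=6))
        fwd = DifferentialExpression(out.counts, out.samples,
                                     ("EE", "1h"), ("B", "1h")).fit()
        rev = DifferentialExpression(out.counts, out.samples,
                                     ("B", "1h"), ("EE", "1h")).fit()
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-10)
        np.testing.assert_allclose(fwd.p_values, rev.p_values, atol=1e-12)
        assert (fwd.n_up, fwd.n_down) == (rev.n_down, rev.n_up)

    def test_overlapping_groups_rejected(self, default_sim):
        ids = default_sim.samples.select("EE", "1h")
        with pytest.raises(ValueError, match="overlap"):
            DifferentialExpression(default_sim.counts, default_sim.samples,
                                   ids, ids)

    def test_summary_and_export(self, tmp_path, default_sim):
        res = DifferentialExpression(default_sim.counts, default_sim.samples,
                                     ("EE", "1h"), ("B", "1h")).fit()
        text = res.summary()
        assert "up in A" in text and "welch_logcpm" in text
        res.to_tsv(tmp_path / "de.tsv")
        back = pd.read_csv(tmp_path / "de.tsv", sep="\t", index_col="gene_id")
        assert list(back.columns) == ["log2fc", "p_value", "call"]
        assert len(back) == len(res.table)
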