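import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusewalk.enrichment import EnrichmentConfig
from fusewalk.errors import InvalidInputError
from fusewalk.integration import (
    ExpressionDataset,
    combine_pathway_results,
    deregulation_analysis,
    differential_ranking,
    differential_table,
    truncated_product_W,
    truncated_product_pvalue,
)


def make_dataset(values, n_case, n_ctrl, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
    labels = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), labels, case_group="case")


class TestExpressionDataset:
    def test_group_split(self):
        d = make_dataset(np.zeros((3, 5)), 3, 2)
        assert len(d.case_samples) == 3 and len(d.control_samples) == 2

    def test_single_sample_group_rejected(self):
        with pytest.raises(InvalidInputError):
            make_dataset(np.zeros((3, 3)), 1, 2)

    def test_unlabeled_sample_rejected(self):
        df = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"], columns=list("wxyz"))
        with pytest.raises(InvalidInputError):
            ExpressionDataset(df, {"w": "case", "x": "case", "y": "control"})

    def test_duplicate_gene_rejected(self):
        df = pd.DataFrame(np.zeros((2, 4)), index=["a", "a"], columns=list("wxyz"))
        with pytest.raises(InvalidInputError):
            ExpressionDataset(df, {s: "case" if s in "wx" else "control" for s in "wxyz"})


class TestDifferentialRanking:
    def test_upshifted_gene_tops_list(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 10))
        values[7, :5] += 5.0
        r = differential_ranking(make_dataset(values, 5, 5))
        assert r.genes[0] == "g7"

    def test_label_swap_reverses_order(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 8))
        d1 = make_dataset(values, 4, 4)
        # swap: controls first -> same matrix, groups flipped
        swapped = np.concatenate([values[:, 4:], values[:, :4]], axis=1)
        d2 = make_dataset(swapped, 4, 4)
        r1 = differential_ranking(d1)
        r2 = differential_ranking(d2)
        assert r1.genes == list(reversed(r2.genes))

    def test_zero_variance_gene_flagged(self):
        values = np.random.default_rng(2).normal(size=(5, 6))
        values[3, :] = 1.0
        t = differential_table(make_dataset(values, 3, 3))
        assert t.loc["g3", "zero_variance"]
        assert t.loc["g3", "p"] == 1.0 and t.loc["g3", "effect"] == 0.0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(400, 40))
        t = differential_table(make_dataset(values, 20, 20))
        assert stats.kstest(t["p"], "uniform").pvalue > 0.01


class TestTruncatedProductW:
    def test_one_factor(self):
        assert truncated_product_W(0.001, 0.5, 0.01) == 0.001

    def test_two_factors(self):
        assert truncated_product_W(0.005, 0.005, 0.01) == pytest.approx(2.5e-5)

    def test_empty_product(self):
        assert truncated_product_W(0.5, 0.5, 0.01) == 1.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            truncated_product_W(bad, 0.5, 0.01)


class TestTruncatedProductPvalue:
    def test_w_one_convention(self):
        assert truncated_product_pvalue(1.0, 0.01) == 1.0

    @pytest.mark.parametrize("tau", [0.01, 0.05])
    @pytest.mark.parametrize("w", [1e-6, 1e-5, 1e-4, 5e-3])
    def test_matches_monte_carlo(self, w, tau):
        rng = np.random.default_rng(17)
        u = rng.random((100_000, 2))
        W = np.where(u <= tau, u, 1.0).prod(axis=1)
        mc = float((W <= w).mean())
        cf = truncated_product_pvalue(w, tau)
        se = np.sqrt(max(mc, 1e-12) * (1 - mc) / 100_000)
        assert abs(cf - mc) <= max(3 * se, 3e-5)

    def test_monotone_in_each_p(self):
        tau = 0.01
        grid = [0.0005, 0.002, 0.008, 0.05, 0.4]
        for p2 in grid:
            last = 0.0
            for p1 in grid:
                pc = truncated_product_pvalue(truncated_product_W(p1, p2, tau), tau)
                assert pc >= last - 1e-15
                last = pc

    def test_null_rate_at_tau_005(self):
        # exact calibration requires alpha <= Pr(W < 1); at tau = 0.05
        # that bound is 0.0975 so the 0.05 rate is directly checkable
        rng = np.random.default_rng(23)
        tau = 0.05
        u = rng.random((10_000, 2))
        rate = np.mean(
            [
                truncated_product_pvalue(truncated_product_W(p1, p2, tau), tau) <= 0.05
                for p1, p2 in u
            ]
        )
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) <= half_width

    def test_null_rate_capped_at_tau_001(self):
        # at tau = 0.01 the combined p never lands in (0.0199, 1), so the
        # rejection rate at alpha = 0.05 equals Pr(W < 1) = 1 - 0.99^2
        rng = np.random.default_rng(29)
        tau = 0.01
        u = rng.random((10_000, 2))
        rate = np.mean(
            [
                truncated_product_pvalue(truncated_product_W(p1, p2, tau), tau) <= 0.05
                for p1, p2 in u
            ]
        )
        expected = 1 - (1 - tau) ** 2  # 0.0199
        assert abs(rate - expected) <= 2.576 * np.sqrt(expected * (1 - expected) / 10_000)

    @pytest.mark.parametrize("bad", [0.0, 1.2])
    def test_invalid_w_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            truncated_product_pvalue(bad, 0.01)


class TestDeregulationAnalysis:
    def test_planted_pathway_minimal_p(self, small_scenario):
        b = small_scenario
        df = deregulation_analysis(b.expression, b.pathways, EnrichmentConfig(n_perm=300, rng_seed=2))
        assert df.iloc[0]["pathway"] == "PLANTED_MODULE"
        assert df.iloc[0]["p"] == df["p"].min()

    def test_deterministic(self, small_scenario):
        b = small_scenario
        cfg = EnrichmentConfig(n_perm=200, rng_seed=5)
        assert deregulation_analysis(b.expression, b.pathways, cfg).equals(
            deregulation_analysis(b.expression, b.pathways, cfg)
        )


class TestCombine:
    @staticmethod
    def table(rows):
        return pd.DataFrame([{"pathway": n, "p": p} for n, p in rows])

    def test_monotone_ordering(self):
        assoc = self.table([("A", 0.001), ("B", 0.001)])
        dereg = self.table([("A", 0.002), ("B", 0.5)])
        df = combine_pathway_results(assoc, dereg, tau=0.01)
        assert df.iloc[0]["pathway"] == "A"
        assert df.iloc[0]["p_combined"] < df.iloc[1]["p_combined"]

    def test_argument_symmetry(self):
        a = self.table([("A", 0.004), ("B", 0.2)])
        d = self.table([("A", 0.009), ("B", 0.003)])
        df1 = combine_pathway_results(a, d)
        df2 = combine_pathway_results(d, a)
        assert (df1["W"].values == df2["W"].values).all()
        assert (df1["p_combined"].values == df2["p_combined"].values).all()

    def test_unmatched_reported_and_excluded(self):
        a = self.table([("A", 0.004), ("ONLY_A", 0.01)])
        d = self.table([("A", 0.009), ("ONLY_D", 0.02)])
        df = combine_pathway_results(a, d)
        assert df["pathway"].tolist() == ["A"]
        assert df.attrs["unmatched"] == ["ONLY_A", "ONLY_D"]

    def test_empty_join_fatal(self):
        with pytest.raises(InvalidInputError):
            combine_pathway_results(self.table([("A", 0.1)]), self.table([("B", 0.1)]))

    def test_w_one_iff_both_exceed_tau(self):
        a = self.table([("A", 0.02), ("B", 0.005)])
        d = self.table([("A", 0.03), ("B", 0.04)])
        df = combine_pathway_results(a, d, tau=0.01).set_index("pathway")
        assert df.loc["A", "W"] == 1.0 and df.loc["A", "p_combined"] == 1.0
        assert df.loc["B", "W"] == 0.005
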