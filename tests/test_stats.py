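"""Gene-set selection, GO overrepresentation, correlations, group tests."""

import numpy as np
import pandas as pd
import pytest

import tissuespec as ts
from tissuespec.synthetic import PLANTED_HIGH_TAU_TERMS
from tissuespec.stats import summarize_by_max_tissue


class TestExtremeSets:
    def test_basic_selection(self):
        tau = pd.Series({"A": 0.9, "B": 0.1, "C": 0.5})
        high, low = ts.select_tau_extreme_sets(tau, k=1)
        assert high == ["A"] and low == ["B"]

    def test_all_equal_resolved_lexicographically(self):
        tau = pd.Series(0.5, index=list("fedcba"))
        high, low = ts.select_tau_extreme_sets(tau, k=3)
        assert sorted(low) == ["a", "b", "c"]
        assert sorted(high) == ["d", "e", "f"]
        assert not set(high) & set(low)

    def test_half_split_partitions(self):
        tau = pd.Series(np.linspace(0, 1, 10), index=[f"g{i}" for i in range(10)])
        high, low = ts.select_tau_extreme_sets(tau, k=5)
        assert set(high) | set(low) == set(tau.index)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            ts.select_tau_extreme_sets(pd.Series({"A": 0.1, "B": 0.2}), k=2)


class TestEnrichment:
    def test_worked_hypergeometric_case(self):
        # universe of 10, term annotates 4, set of 5 holds all 4:
        # p = C(4,4) C(6,1) / C(10,5) = 6/252
        universe = [f"g{i}" for i in range(10)]
        annotations = {g: {"T"} if i < 4 else set() for i, g in enumerate(universe)}
        gene_set = universe[:5]
        result = ts.go_overrepresentation(gene_set, universe, annotations)
        p = result.set_index("term_id").loc["T", "p_raw"]
        assert p == pytest.approx(6 / 252, rel=1e-12)

    def test_set_equal_universe_gives_p_one(self):
        universe = ["a", "b", "c"]
        annotations = {"a": {"T1"}, "b": {"T1", "T2"}, "c": set()}
        result = ts.go_overrepresentation(universe, universe, annotations)
        assert (result["p_raw"] == 1.0).all()

    def test_absent_term_counts(self):
        universe = ["a", "b"]
        annotations = {"a": {"T"}, "b": set()}
        result = ts.go_overrepresentation(["b"], universe, annotations)
        row = result.set_index("term_id").loc["T"]
        assert row["set_count"] == 0 and row["p_raw"] == 1.0

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            ts.go_overrepresentation(["x"], ["a"], {"a": set()})

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(60)]
        annotations = {
            g: {f"T{j}" for j in rng.integers(0, 12, size=3)} for g in universe
        }
        result = ts.go_overrepresentation(universe[:15], universe, annotations)
        assert (result["p_adjusted"] >= result["p_raw"] - 1e-15).all()
        ordered = result.sort_values("p_raw")
        assert ordered["p_adjusted"].is_monotonic_increasing

    def test_semicolon_string_annotations_accepted(self):
        universe = ["a", "b"]
        result = ts.go_overrepresentation(
            ["a"], universe, pd.Series({"a": "T1;T2", "b": "T2"})
        )
        assert set(result["term_id"]) == {"T1", "T2"}

    def test_planted_terms_rank_above_background(self):
        """Terms planted in high-tau genes outrank background terms in the
        high-tau enrichment in >= 95% of repetitions."""
        successes = 0
        n_rep = 50
        for rep in range(n_rep):
            truth = ts.generate_gene_catalog(
                ts.SimulationConfig(n_genes=300, seed=700 + rep)
            )
            genes = truth.genes
            high, _ = ts.select_tau_extreme_sets(genes["true_tau"], k=60)
            result = ts.go_overrepresentation(
                high, genes.index, genes["go_terms"]
            ).reset_index(drop=True)
            ranks = {t: i for i, t in enumerate(result["term_id"])}
            planted = [ranks[t] for t in PLANTED_HIGH_TAU_TERMS if t in ranks]
            background = [
                r for t, r in ranks.items() if t.startswith("GO:BG")
            ]
            if planted and np.mean(planted) < np.mean(background):
                successes += 1
        assert successes >= 0.95 * n_rep


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        res = ts.correlate([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.df == 1

    def test_spearman_hand_example(self):
        res = ts.correlate([1, 2, 3], [10, 1, 5], method="spearman")
        assert res.r == pytest.approx(-0.5)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(40), rng.random(40)
        base = ts.correlate(x, y, method="spearman").r
        warped = ts.correlate(np.exp(5 * x), y**3, method="spearman").r
        assert warped == pytest.approx(base, abs=1e-12)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            ts.correlate([1, 2, 3], [5, 5, 5])

    def test_log_transform(self):
        res = ts.correlate(
            [1, 10, 100], [0, 1, 2], transform=("log", "none")
        )
        assert res.r == pytest.approx(1.0)


class TestGroupCompare:
    def test_kruskal_hand_example(self):
        res = ts.group_compare({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.statistic == pytest.approx(3.857, abs=0.001)
        assert res.df == (1,)

    def test_identical_groups_null(self):
        res = ts.group_compare([[2, 2, 2], [2, 2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0
        res_f = ts.group_compare([[2, 2, 2], [2, 2, 2]], method="anova")
        assert res_f.statistic == 0.0

    def test_six_groups_df_five(self):
        rng = np.random.default_rng(3)
        groups = [rng.random(10) for _ in range(6)]
        assert ts.group_compare(groups).df == (5,)
        assert ts.group_compare(groups, method="anova").df == (5, 54)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            ts.group_compare([[1.0]])


class TestTissueSummary:
    def _tables(self, omegas_by_tissue, n_per=10, seed=0):
        rng = np.random.default_rng(seed)
        rows, gene_rows = [], []
        for tissue, mean_omega in omegas_by_tissue.items():
            for i in range(n_per):
                gid = f"{tissue}_{i}"
                rows.append(
                    {"entity_id": gid, "tau": rng.uniform(0.2, 0.8),
                     "max_tissue": tissue}
                )
                gene_rows.append(
                    {"gene_id": gid,
                     "omega": max(0.0, rng.normal(mean_omega, 0.01))}
                )
        tau_table = pd.DataFrame(rows).set_index("entity_id")
        gene_records = pd.DataFrame(gene_rows).set_index("gene_id")
        return tau_table, gene_records

    def test_lowest_omega_group_identified(self):
        tau_table, gene_records = self._tables(
            {"embryo": 0.05, "liver": 0.2, "testes": 0.3}
        )
        summary = summarize_by_max_tissue(
            tau_table, gene_records, n_boot=500, seed=1
        )
        assert summary["mean_omega"].idxmin() == "embryo"
        # CI bounds bracket the mean
        assert (summary["omega_ci_low"] <= summary["mean_omega"]).all()
        assert (summary["omega_ci_high"] >= summary["mean_omega"]).all()

    def test_small_groups_get_na_ci(self):
        tau_table, gene_records = self._tables({"embryo": 0.1}, n_per=2)
        summary = summarize_by_max_tissue(tau_table, gene_records, n_boot=100)
        assert np.isnan(summary.loc["embryo", "omega_ci_low"])

    def test_constant_omega_zero_width_ci(self):
        tau_table, gene_records = self._tables({"liver": 0.2}, n_per=5)
        gene_records["omega"] = 0.15
        summary = summarize_by_max_tissue(tau_table, gene_records, n_boot=200)
        assert summary.loc["liver", "omega_ci_low"] == pytest.approx(0.15)
        assert summary.loc["liver", "omega_ci_high"] == pytest.approx(0.15)
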