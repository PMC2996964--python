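"""Generator: determinism, limits, conservation laws, truth consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import tissuespec as ts
from tissuespec.tau import compute_tau_matrix


class TestConfig:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            ts.SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            ts.SimulationConfig(library_sizes=(100,) * 5)  # wrong length
        with pytest.raises(ValueError):
            ts.SimulationConfig(contaminant_fraction=1.0)
        with pytest.raises(ValueError):
            ts.SimulationConfig(profile_concentration=0.0)


class TestCatalog:
    def test_same_seed_identical(self):
        config = ts.SimulationConfig(n_genes=120, seed=5)
        a = ts.simulate_study(config)
        b = ts.simulate_study(config)
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
        pd.testing.assert_frame_equal(a.contig_table, b.contig_table)
        pd.testing.assert_frame_equal(a.alignments, b.alignments)

    def test_uniform_limit_tau_near_zero(self):
        config = ts.SimulationConfig(
            n_genes=200, seed=1, profile_concentration=1e6,
            profile_concentration_broad=None, profile_zero_threshold=0.0,
        )
        truth = ts.generate_gene_catalog(config)
        assert truth.genes["true_tau"].max() < 0.05

    def test_one_hot_limit_tau_near_max(self):
        config = ts.SimulationConfig(
            n_genes=200, seed=1, profile_concentration=1e-3,
            profile_concentration_broad=None,
        )
        truth = ts.generate_gene_catalog(config)
        assert truth.genes["true_tau"].median() > 0.85
        assert truth.genes["true_tau"].min() > 0.6

    def test_proportions_sum_to_one(self):
        truth = ts.generate_gene_catalog(ts.SimulationConfig(n_genes=50, seed=2))
        np.testing.assert_allclose(truth.proportions.sum(axis=1), 1.0)

    def test_true_tau_is_tau_of_expected_tpm(self, small_study):
        recomputed = compute_tau_matrix(
            small_study.truth.expected_tpm.to_numpy(float)
        )
        np.testing.assert_array_equal(
            recomputed, small_study.truth.genes["true_tau"].to_numpy()
        )

    def test_omega_tau_coupling_positive(self):
        truth = ts.generate_gene_catalog(ts.SimulationConfig(n_genes=2000, seed=3))
        rho = spearmanr(
            np.log(truth.genes["omega"] + 1), truth.genes["true_tau"]
        ).statistic
        assert rho > 0.2


class TestReadCounts:
    def test_column_sums_equal_library_sizes(self, small_study):
        assert (
            small_study.gene_counts.sum(axis=0).to_numpy()
            == np.array(small_study.config.library_sizes)
        ).all()

    def test_single_gene_gets_all_reads(self):
        config = ts.SimulationConfig(n_genes=1, seed=4)
        truth = ts.generate_gene_catalog(config)
        counts = ts.simulate_read_counts(truth, config)
        assert (counts.iloc[0].to_numpy() == np.array(config.library_sizes)).all()

    def test_multinomial_mean_recovered(self):
        """Empirical mean count over replicates stays within 3 standard
        errors of library_size * p for every gene x tissue cell."""
        config = ts.SimulationConfig(
            n_genes=25, n_tissues=3, library_sizes=(3000, 2500, 2000), seed=6
        )
        truth = ts.generate_gene_catalog(config)
        n_rep = 1000
        total = np.zeros((25, 3))
        for k in range(n_rep):
            rep = dataclasses.replace(config, seed=10_000 + k)
            total += ts.simulate_read_counts(truth, rep).to_numpy()
        mean = total / n_rep
        p = truth.expected_tpm.to_numpy() / 1e6
        expected = p * np.array(config.library_sizes)[None, :]
        se = np.sqrt(expected * (1 - p) / n_rep)
        z = np.abs(mean - expected) / (se + 1e-12)
        # per-cell 3-se check, allowing the expected handful of exceedances
        # across 75 simultaneous cells
        assert (z <= 3).mean() >= 0.95
        assert z.max() < 5


class TestFragmentation:
    def test_read_conservation_per_gene_per_tissue(self, small_study):
        counts = small_study.contig_counts
        gene_of = pd.Series(small_study.contig_to_gene)
        regrouped = counts.loc[gene_of.index].groupby(gene_of).sum()
        expressed = small_study.gene_counts[small_study.gene_counts.sum(axis=1) > 0]
        pd.testing.assert_frame_equal(
            regrouped.sort_index(), expressed.sort_index(),
            check_dtype=False, check_names=False,
        )

    def test_zero_mean_gives_one_contig_per_gene(self):
        config = ts.SimulationConfig(
            n_genes=100, seed=7, contigs_per_gene_mean=0.0,
            contaminant_fraction=0.0,
        )
        truth = ts.generate_gene_catalog(config)
        counts = ts.simulate_read_counts(truth, config)
        table, mapping, contaminants = ts.fragment_into_contigs(
            counts, truth, config
        )
        expressed = (counts.sum(axis=1) > 0).sum()
        assert len(table) == expressed
        assert len(set(mapping.values())) == expressed
        assert contaminants == []

    def test_contig_lengths_bounded_by_transcript(self, small_study):
        lengths = small_study.contig_table["length"]
        gene_len = small_study.truth.genes["length_bp"]
        for contig, gene in small_study.contig_to_gene.items():
            assert lengths[contig] <= gene_len[gene]

    def test_contaminants_absent_from_truth_map(self, small_study):
        assert len(small_study.contaminant_ids) > 0
        assert not set(small_study.contaminant_ids) & set(
            small_study.contig_to_gene
        )


class TestFixtureBundle:
    def test_round_trip(self, small_study, tmp_path):
        paths = ts.write_fixture_bundle(small_study, tmp_path / "bundle")
        back = ts.read_fixture_bundle(tmp_path / "bundle")
        pd.testing.assert_frame_equal(
            back["contig_counts"], small_study.contig_table
        )
        pd.testing.assert_frame_equal(
            back["gene_counts"], small_study.gene_counts
        )
        assert back["truth_map"].to_dict() == small_study.contig_to_gene
        assert back["contaminant_subjects"] == small_study.contaminant_subjects
        assert set(paths) >= {"contig_counts", "annotation", "alignments"}

    def test_decoy_hits_above_cutoff(self, small_study):
        aln = small_study.alignments
        best = aln.sort_values("evalue").groupby("qseqid").first()
        decoys = aln[aln["evalue"] > 1e-44]
        assert (decoys["evalue"] > 1e-10).all()
        # every non-contaminant contig's best hit is its true gene
        for contig, gene in small_study.contig_to_gene.items():
            assert best.loc[contig, "sseqid"] == gene

    def test_alignment_file_parses(self, small_study, tmp_path):
        paths = ts.write_fixture_bundle(small_study, tmp_path / "bundle")
        hits = ts.parse_tabular_alignments(paths["alignments"])
        assert {h.query_id for h in hits} == set(small_study.contig_table.index)


class TestCoupledContigs:
    def test_no_coupling_independence(self):
        table = ts.simulate_coupled_contigs(
            4000, 0.0, (10**5,) * 6, seed=9, depth_range=(10**4, 10**5)
        )
        totals = table.sum(axis=1)
        taus = compute_tau_matrix(
            table.to_numpy() / 1e5 * 1e6
        )
        r = np.corrcoef(np.log10(totals), taus)[0, 1]
        # deep coverage + no planted coupling: only tau's intrinsic
        # dependence on scale remains
        assert abs(r) < 0.15

    def test_negative_coupling_visible(self):
        table = ts.simulate_coupled_contigs(
            4000, -0.5, (10**5,) * 6, seed=9, depth_range=(10**4, 10**5)
        )
        totals = table.sum(axis=1)
        taus = compute_tau_matrix(table.to_numpy() / 1e5 * 1e6)
        assert np.corrcoef(np.log10(totals), taus)[0, 1] < -0.2
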