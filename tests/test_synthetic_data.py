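"""Generators and the Wright-Fisher bottleneck simulator."""

import numpy as np
import pytest


from tetramate.marker_alleles import call_genotype, cluster_alleles, map_catalog_labels
from tetramate.mating_model import compare_matrices, predict_matrix
from tetramate.synthetic_data import (
    SimConfig,
    WrightFisherConfig,
    make_allele_sequences,
    simulate_cross_matrix,
    simulate_population,
    simulate_spore_family,
    simulate_wright_fisher,
    wright_fisher_retention,
)
from tetramate.types import GenotypeFlag, Locus, Ploidy, Source

from conftest import dika

PARENT = dika("parent", ["A1", "A3"], ["B2", "B3"])


class TestAlleleSequences:
    def test_divergence_within_binomial_bounds(self):
        """3 alleles at 5% divergence: pairwise identity in (0.85, 0.99)."""
        cfg = SimConfig(seed=1, n_alleles_a=3, marker_len=500,
                        inter_allele_divergence=0.05)
        catalog = make_allele_sequences(cfg)[Locus.MAT_A]
        seqs = [seq for _, seq in catalog.alleles]
        assert len(set(seqs)) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                ident = np.mean(
                    [a == b for a, b in zip(seqs[i], seqs[j])]
                )
                assert 0.85 < ident < 0.99

    def test_single_allele_is_ancestor(self):
        cfg = SimConfig(seed=2, n_alleles_a=1, n_alleles_b=1)
        catalogs = make_allele_sequences(cfg)
        assert len(catalogs[Locus.MAT_A].alleles) == 1

    def test_determinism(self):
        cfg = SimConfig(seed=3)
        assert (
            make_allele_sequences(cfg)[Locus.MAT_B].alleles
            == make_allele_sequences(SimConfig(seed=3))[Locus.MAT_B].alleles
        )

    def test_seed_changes_output(self):
        a = make_allele_sequences(SimConfig(seed=4))[Locus.MAT_A].alleles
        b = make_allele_sequences(SimConfig(seed=5))[Locus.MAT_A].alleles
        assert a != b

    def test_zero_divergence_with_multiple_alleles_rejected(self):
        with pytest.raises(ValueError, match="divergence 0"):
            make_allele_sequences(SimConfig(inter_allele_divergence=0.0))


class TestSimulatePopulation:
    def test_zero_dropout_yields_complete_dikaryons(self):
        cfg = SimConfig(seed=6, n_strains=30, clone_dropout=0.0, marker_len=80)
        table, reads, _ = simulate_population(cfg)
        for entry in table:
            assert entry.ploidy is Ploidy.dikaryon
            assert len(entry.a_alleles) == 2
            assert len(entry.b_alleles) == 2

    def test_truth_table_satisfies_genotype_invariants(self):
        cfg = SimConfig(seed=16, n_strains=40, prop_monokaryon=0.3, marker_len=80)
        table, _, _ = simulate_population(cfg)
        for entry in table:
            if entry.ploidy is Ploidy.dikaryon:
                # dikaryons are heteroallelic at both loci by construction
                assert len(entry.a_alleles) == 2
                assert len(entry.b_alleles) == 2

    def test_single_allele_rate_matches_closed_form(self):
        """Per-clone uniform allele pick with dropout d: one specific
        allele of a pair stays unseen with p = ((1+d)/2)^k, so
        P(exactly one allele seen) = 2(((1+d)/2)^k - d^k)."""
        d, k = 0.5, 8
        cfg = SimConfig(seed=7, n_strains=400, clone_dropout=d,
                        clones_per_marker=k, marker_len=60)
        table, reads, catalogs = simulate_population(cfg)
        observed = _called_genotypes(table, reads, catalogs)
        n_single = sum(
            1 for g in observed.values() if GenotypeFlag.A_SINGLE in g.flags
        )
        p_one = 2 * (((1 + d) / 2) ** k - d**k)
        sd = np.sqrt(400 * p_one * (1 - p_one))
        assert abs(n_single - 400 * p_one) < 4 * sd

    def test_end_to_end_recovery_without_noise(self):
        """cluster + call on clean reads reproduces the truth table."""
        cfg = SimConfig(seed=8, n_strains=25, clone_dropout=0.0,
                        seq_error_rate=0.0, marker_len=100)
        table, reads, catalogs = simulate_population(cfg)
        observed = _called_genotypes(table, reads, catalogs)
        for entry in table:
            called = observed[entry.strain_id]
            assert called.a_alleles == entry.a_alleles
            assert called.b_alleles == entry.b_alleles

    def test_monomorphic_locus_with_dikaryons_rejected(self):
        cfg = SimConfig(seed=9, n_alleles_a=1, prop_monokaryon=0.5,
                        inter_allele_divergence=0.05)
        with pytest.raises(ValueError, match="heteroallelic"):
            simulate_population(cfg)


def _called_genotypes(table, reads, catalogs):
    """Run the calling pipeline on simulated reads, pinning cluster
    labels to the simulation's allele names."""
    called = {}
    labels_by_strain: dict[str, dict[Locus, list[str]]] = {}
    for locus in Locus:
        locus_reads = [r for r in reads if r.locus is locus]
        if not locus_reads:
            continue
        catalog, assignment = cluster_alleles(locus_reads, min_identity=1.0)
        ref = {seq: label for label, seq in catalogs[locus].alleles}
        _, label_map = map_catalog_labels(catalog, ref)
        for idx, read in enumerate(locus_reads):
            labels_by_strain.setdefault(read.strain_id, {}).setdefault(
                locus, []
            ).append(label_map[assignment[idx]])
    for entry in table:
        called[entry.strain_id] = call_genotype(
            entry.strain_id, entry.ploidy,
            labels_by_strain.get(entry.strain_id, {}),
        )
    return called


class TestSporeFamily:
    def test_fair_family_class_frequencies(self):
        cfg = SimConfig(seed=10, family_size=4000, recomb_fraction=0.5)
        family = simulate_spore_family(PARENT, cfg)
        counts = {}
        for child in family.progeny:
            key = (min(child.a_alleles), min(child.b_alleles))
            counts[key] = counts.get(key, 0) + 1
        sd = np.sqrt(4000 * 0.25 * 0.75)
        assert len(counts) == 4
        for n in counts.values():
            assert abs(n - 1000) < 4 * sd

    def test_complete_linkage_only_parental_classes(self):
        cfg = SimConfig(seed=11, family_size=200, recomb_fraction=0.0)
        family = simulate_spore_family(PARENT, cfg)
        classes = {
            (min(c.a_alleles), min(c.b_alleles)) for c in family.progeny
        }
        assert classes == {("A1", "B2"), ("A3", "B3")}

    def test_determinism(self):
        cfg = SimConfig(seed=12, family_size=23)
        a = simulate_spore_family(PARENT, cfg)
        b = simulate_spore_family(PARENT, cfg)
        assert [c.strain_id for c in a.progeny] == [c.strain_id for c in b.progeny]
        assert [c.a_alleles for c in a.progeny] == [c.a_alleles for c in b.progeny]

    def test_distortion_validation(self):
        with pytest.raises(ValueError, match="distortion"):
            SimConfig(distortion=[1, -1, 1, 1])


class TestCrossMatrix:
    def _sibs(self, n=16):
        cfg = SimConfig(seed=14, family_size=n)
        return simulate_spore_family(PARENT, cfg).progeny

    def test_error_free_matrix_matches_prediction(self):
        sibs = self._sibs()
        observed = simulate_cross_matrix(sibs, 0.0, 0.0, seed=1)
        report = compare_matrices(predict_matrix(sibs), observed)
        assert report.n_mismatch == 0
        assert report.n_unresolved == 0

    def test_error_rate_within_binomial_bounds(self):
        sibs = self._sibs(16)  # 120 pairs
        observed = simulate_cross_matrix(sibs, 0.1, 0.0, seed=2)
        report = compare_matrices(predict_matrix(sibs), observed)
        sd = np.sqrt(120 * 0.1 * 0.9)
        assert abs(report.n_mismatch - 12) < 4 * sd

    def test_all_unresolved(self):
        sibs = self._sibs(8)
        observed = simulate_cross_matrix(sibs, 0.0, 1.0, seed=3)
        report = compare_matrices(predict_matrix(sibs), observed)
        assert report.n_pairs_scored == 0
        assert report.n_unresolved == len(sibs) * (len(sibs) - 1) // 2

    def test_symbols_and_symmetry(self):
        sibs = self._sibs(10)
        observed = simulate_cross_matrix(sibs, 0.2, 0.2, seed=4)
        for a, b in observed.pairs():
            assert observed.get(a, b) is observed.get(b, a)


class TestWrightFisher:
    def test_determinism(self):
        cfg = WrightFisherConfig(seed=5, pop_size=60, total_gens=15,
                                 bottleneck_gen=8, bottleneck_size=10)
        r1 = simulate_wright_fisher(cfg)
        r2 = simulate_wright_fisher(cfg)
        assert r1.trajectories.equals(r2.trajectories)

    def test_no_bottleneck_symmetric_mean_frequencies(self):
        """Without a bottleneck each MAT allele hovers near 1/k."""
        cfg = WrightFisherConfig(
            seed=6, pop_size=300, bottleneck_size=300, bottleneck_gen=10,
            total_gens=40, n_mat_a=3, n_mat_b=3, n_neutral=3,
        )
        result = simulate_wright_fisher(cfg)
        mat_a = result.trajectories.query("locus == 'MAT_A'")
        means = mat_a.groupby("allele")["frequency"].mean()
        assert np.allclose(means, 1 / 3, atol=0.08)

    def test_bottleneck_reduces_population_then_recovers(self):
        cfg = WrightFisherConfig(seed=7, pop_size=100, bottleneck_size=5,
                                 bottleneck_gen=3, total_gens=6)
        result = simulate_wright_fisher(cfg)
        assert result.richness.query("generation == 6").shape[0] == 3

    def test_initial_single_mat_allele_rejected(self):
        with pytest.raises(ValueError, match="MAT"):
            WrightFisherConfig(n_mat_a=1)

    def test_mat_richness_outlives_neutral_through_bottleneck(self):
        """Negative frequency-dependent selection keeps MAT alleles
        through the bottleneck more often than the drifting neutral
        locus (40 quick replicates; the full 100-replicate test lives
        with the acceptance checks)."""
        cfg = WrightFisherConfig(seed=8)
        df = wright_fisher_retention(cfg, n_replicates=40)
        frac = df.groupby("locus")["retained_all"].mean()
        assert frac["MAT_A"] > frac["neutral"]
        assert frac["MAT_B"] > frac["neutral"]

    def test_mean_post_bottleneck_richness_ordering(self):
        cfg = WrightFisherConfig(seed=9)
        df = wright_fisher_retention(cfg, n_replicates=40)
        mean_final = df.groupby("locus")["final_richness"].mean()
        assert mean_final["MAT_A"] >= mean_final["neutral"]
        assert mean_final["MAT_B"] >= mean_final["neutral"]
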