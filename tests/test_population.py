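"""Population richness, frequencies, outcrossing, founders, and audit."""

import random

import numpy as np
import pytest

from tetramate.population import (
    allele_frequencies,
    allele_richness,
    exhaustive_minimal_founders,
    founders_cover,
    marker_resolution_audit,
    minimal_founders,
    outcrossing_potential,
    single_allele_strain_counts,
)
from tetramate.synthetic_data import SimConfig, simulate_population
from tetramate.types import FunctionalProxyPair, Locus, PopulationTable

from conftest import dika, mono


class TestRichness:
    def test_european_population(self, european_table, functional_pairs):
        from tetramate.reproduce import _combined_population

        richness = allele_richness(_combined_population())
        assert richness[Locus.MAT_A] == 3
        assert richness[Locus.MAT_B] == 4

    def test_single_strain(self):
        richness = allele_richness(PopulationTable([mono("s", "A1", "B1")]))
        assert richness == {Locus.MAT_A: 1, Locus.MAT_B: 1}

    def test_empty_locus_warns_zero(self):
        table = PopulationTable([dika("d", ["A1", "A2"], [])])
        with pytest.warns(UserWarning, match="no data"):
            richness = allele_richness(table)
        assert richness[Locus.MAT_B] == 0

    def test_three_allele_strains_counted_in_richness(self, european_table):
        # the triple-A strains contribute all their alleles to richness
        assert allele_richness(european_table)[Locus.MAT_A] == 3


class TestFrequencies:
    def test_monomorphic(self):
        table = PopulationTable([mono("s1", "A1", "B1"), mono("s2", "A1", "B1")])
        freqs = allele_frequencies(table)
        assert freqs[Locus.MAT_A] == {"A1": 1.0}

    def test_gene_count_mixed_ploidy(self):
        table = PopulationTable(
            [dika("d", ["A1", "A3"], ["B1", "B2"]), mono("m", "A1", "B1")]
        )
        freqs = allele_frequencies(table, mode="gene_count")
        assert freqs[Locus.MAT_A] == pytest.approx({"A1": 2 / 3, "A3": 1 / 3})

    def test_strain_presence_mode(self):
        table = PopulationTable(
            [dika("d", ["A1", "A3"], ["B1", "B2"]), mono("m", "A1", "B1")]
        )
        freqs = allele_frequencies(table, mode="strain_presence")
        assert freqs[Locus.MAT_A] == pytest.approx({"A1": 2 / 3, "A3": 1 / 3})

    def test_sum_to_one_on_random_tables(self):
        """Both modes normalise per locus, 500 random tables."""
        rng = random.Random(8)
        for _ in range(500):
            entries = []
            for i in range(rng.randint(1, 12)):
                if rng.random() < 0.5:
                    entries.append(
                        mono(f"m{i}", f"A{rng.randint(1, 4)}", f"B{rng.randint(1, 4)}")
                    )
                else:
                    a = rng.sample(["A1", "A2", "A3", "A4"], rng.choice([1, 2, 3]))
                    b = rng.sample(["B1", "B2", "B3", "B4"], rng.choice([1, 2]))
                    entries.append(dika(f"d{i}", a, b))
            table = PopulationTable(entries)
            for mode in ("gene_count", "strain_presence"):
                with np.errstate(all="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        freqs = allele_frequencies(table, mode=mode)
                for locus in Locus:
                    if freqs[locus]:
                        assert sum(freqs[locus].values()) == pytest.approx(1.0)

    def test_parameter_recovery_from_simulation(self):
        """Estimates from a 500-strain simulated table fall within 3 SE
        of the generating frequencies."""
        truth_a = [0.5, 0.3, 0.2]
        cfg = SimConfig(
            seed=13, n_strains=500, prop_monokaryon=1.0,
            allele_freqs_a=truth_a, marker_len=60,
        )
        table, _, _ = simulate_population(cfg)
        freqs = allele_frequencies(table, mode="gene_count")
        for label, p in zip(["A1", "A2", "A3"], truth_a):
            se = np.sqrt(p * (1 - p) / 500)
            assert abs(freqs[Locus.MAT_A].get(label, 0.0) - p) < 3 * se


class TestOutcrossing:
    def test_single_allele_per_locus(self):
        assert outcrossing_potential({"A1": 1.0}, {"B1": 1.0}) == 0.0

    def test_equifrequent_closed_form(self):
        freqs_a = {f"A{i}": 1 / 3 for i in range(3)}
        freqs_b = {f"B{i}": 1 / 4 for i in range(4)}
        assert outcrossing_potential(freqs_a, freqs_b) == pytest.approx(0.5)

    def test_monte_carlo_agreement(self):
        """Empirical compatible fraction of 1e5 sampled pairs within
        0.01 of the closed form."""
        rng = np.random.default_rng(5)
        freqs_a = {"A1": 0.5, "A2": 0.3, "A3": 0.2}
        freqs_b = {"B1": 0.4, "B2": 0.3, "B3": 0.2, "B4": 0.1}
        n = 100_000
        a = rng.choice(3, size=(n, 2), p=list(freqs_a.values()))
        b = rng.choice(4, size=(n, 2), p=list(freqs_b.values()))
        empirical = np.mean((a[:, 0] != a[:, 1]) & (b[:, 0] != b[:, 1]))
        assert abs(empirical - outcrossing_potential(freqs_a, freqs_b)) < 0.01

    def test_more_even_frequencies_never_decrease_potential(self):
        """Evening out one vector (same support) raises compatibility."""
        freqs_b = {"B1": 0.5, "B2": 0.5}
        for skew in np.linspace(0.5, 0.95, 10):
            skewed = {"A1": skew, "A2": (1 - skew) / 2, "A3": (1 - skew) / 2}
            even = {"A1": 1 / 3, "A2": 1 / 3, "A3": 1 / 3}
            assert outcrossing_potential(even, freqs_b) >= outcrossing_potential(
                skewed, freqs_b
            ) - 1e-12

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            outcrossing_potential({"A1": 0.7}, {"B1": 1.0})


class TestMinimalFounders:
    def test_european_allele_set_needs_two(self):
        sol = minimal_founders({"A1", "A2", "A3"}, {"B1", "B2", "B3", "B4"})
        assert sol.n_dikaryons == 2
        assert founders_cover(sol, {"A1", "A2", "A3"}, {"B1", "B2", "B3", "B4"})

    def test_singletons_need_one(self):
        sol = minimal_founders({"A1"}, {"B1"})
        assert sol.n_dikaryons == 1

    def test_five_by_two(self):
        a = {f"A{i}" for i in range(1, 6)}
        sol = minimal_founders(a, {"B1", "B2"})
        assert sol.n_dikaryons == 3
        assert founders_cover(sol, a, {"B1", "B2"})

    def test_matches_exhaustive_oracle(self):
        """Closed form equals brute-force search for all nA, nB <= 6,
        and every witness is a valid cover."""
        for n_a in range(1, 7):
            for n_b in range(1, 7):
                a = {f"A{i}" for i in range(n_a)}
                b = {f"B{i}" for i in range(n_b)}
                sol = minimal_founders(a, b)
                assert sol.n_dikaryons == exhaustive_minimal_founders(a, b)
                assert founders_cover(sol, a, b)
                assert len(sol.assignments) == sol.n_dikaryons

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError, match="at least one allele"):
            minimal_founders(set(), {"B1"})


class TestResolutionAudit:
    def test_bundled_table(self, functional_pairs):
        audit = marker_resolution_audit(functional_pairs)
        assert audit.n_functional[Locus.MAT_A] == 4
        assert audit.n_functional[Locus.MAT_B] == 5
        assert audit.unresolved[Locus.MAT_A] == ["A4"]
        assert audit.unresolved[Locus.MAT_B] == ["B5"]
        assert audit.n_unresolved == 2
        assert not audit.inconsistent[Locus.MAT_A]
        assert not audit.inconsistent[Locus.MAT_B]

    def test_bijective_mapping_fully_resolved(self):
        pairs = [
            FunctionalProxyPair(f"s{i}", f"A{i}", f"B{i}", f"pA{i}", f"pB{i}")
            for i in range(1, 4)
        ]
        audit = marker_resolution_audit(pairs)
        assert audit.n_unresolved == 0

    def test_inconsistent_mapping_reported(self):
        pairs = [
            FunctionalProxyPair("s1", "A1", "B1", "pA1", "pB1"),
            FunctionalProxyPair("s2", "A1", "B1", "pA2", "pB1"),
        ]
        audit = marker_resolution_audit(pairs)
        assert audit.inconsistent[Locus.MAT_A] == ["A1"]

    def test_stable_under_permutation(self, functional_pairs):
        rng = random.Random(3)
        shuffled = list(functional_pairs)
        rng.shuffle(shuffled)
        a = marker_resolution_audit(functional_pairs)
        b = marker_resolution_audit(shuffled)
        assert a.mapping == b.mapping
        assert a.unresolved == b.unresolved

    def test_missing_labels_skipped_with_warning(self):
        pairs = [
            FunctionalProxyPair("s1", "", "B1", "pA1", "pB1"),
            FunctionalProxyPair("s2", "A1", "B1", "pA1", "pB1"),
        ]
        with pytest.warns(UserWarning, match="skipped"):
            audit = marker_resolution_audit(pairs)
        assert audit.n_skipped == 1


class TestSingleAlleleConventions:
    def test_both_conventions_on_european_table(self, european_table):
        counts = single_allele_strain_counts(european_table)
        assert counts["all_single"][Locus.MAT_A] == 6
        assert counts["all_single"][Locus.MAT_B] == 3
        assert counts["other_locus_observed"][Locus.MAT_B] == 2
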