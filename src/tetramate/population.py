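"""Population-level mating-type statistics.

Summarises a table of strain genotypes: distinct-allele richness per
locus, allele frequencies under two estimation modes, the probability
that two random monokaryons are mating-compatible, the minimal number of
founding dikaryons able to carry all observed alleles, and an audit of
how well the marker proxies resolve functional mating factors known from
crossing experiments.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

from .types import (
    FunctionalProxyPair,
    GenotypeFlag,
    Locus,
    MatingGenotype,
    Ploidy,
    PopulationTable,
)


def allele_richness(table: PopulationTable) -> dict[Locus, int]:
    """Distinct allele labels observed per locus over all strains.

    Strains missing data at a locus contribute nothing there; a locus
    with no data at all reports 0 with a warning.
    """
    richness: dict[Locus, int] = {}
    for locus in Locus:
        labels = set()
        for entry in table:
            labels |= entry.alleles(locus)
        if not labels:
            warnings.warn(f"no data at {locus.value}; richness reported as 0")
        richness[locus] = len(labels)
    return richness


def allele_frequencies(
    table: PopulationTable, mode: str = "gene_count"
) -> dict[Locus, dict[str, float]]:
    """Per-locus allele frequency estimates.

    ``gene_count``: each monokaryon contributes one allele slot per
    locus and each dikaryon two; a dikaryon observed with a single
    allele is an incomplete observation, so its unobserved slot is
    excluded from the denominator rather than imputed. Dikaryons with
    more than two observed alleles (flagged ``*_EXCESS``) contribute
    only their two clone-supported alleles that are most frequent
    population-wide (richness still counts all three), with a warning.

    ``strain_presence``: each distinct allele counts once per strain
    that carries it.

    Frequencies sum to 1 per locus with any data.
    """
    if mode not in ("gene_count", "strain_presence"):
        raise ValueError(f"unknown mode {mode!r}")
    freqs: dict[Locus, dict[str, float]] = {}
    for locus in Locus:
        presence = Counter()
        for entry in table:
            presence.update(entry.alleles(locus))
        counts: Counter = Counter()
        for entry in table:
            alleles = entry.alleles(locus)
            if not alleles:
                continue
            if mode == "strain_presence":
                counts.update(alleles)
                continue
            if entry.ploidy is Ploidy.monokaryon or len(alleles) <= 2:
                counts.update(alleles)
            else:
                keep = sorted(alleles, key=lambda a: (-presence[a], a))[:2]
                warnings.warn(
                    f"{entry.strain_id}: {len(alleles)} alleles at "
                    f"{locus.value}; gene_count mode keeps {keep}"
                )
                counts.update(keep)
        total = sum(counts.values())
        freqs[locus] = (
            {a: counts[a] / total for a in sorted(counts)} if total else {}
        )
    return freqs


def outcrossing_potential(
    freqs_a: dict[str, float], freqs_b: dict[str, float], atol: float = 1e-8
) -> float:
    """Probability that two random monokaryons are mating-compatible.

    With independent loci this is the probability they differ at both:
    ``(1 - sum_i pA_i^2) * (1 - sum_j pB_j^2)``. Input frequency
    vectors must each sum to 1.
    """
    for name, freqs in (("MAT A", freqs_a), ("MAT B", freqs_b)):
        if not freqs:
            raise ValueError(f"empty frequency vector for {name}")
        total = sum(freqs.values())
        if abs(total - 1.0) > atol:
            raise ValueError(f"{name} frequencies sum to {total}, not 1")
        if any(p < 0 for p in freqs.values()):
            raise ValueError(f"negative frequency in {name}")
    het_a = 1.0 - sum(p * p for p in freqs_a.values())
    het_b = 1.0 - sum(p * p for p in freqs_b.values())
    return het_a * het_b


@dataclass
class FounderSolution:
    """A minimal set of founding dikaryons covering all observed
    alleles; each founder carries at most two distinct alleles per
    locus (a singleton locus is covered with a repeated slot)."""

    n_dikaryons: int
    assignments: list[tuple[tuple[str, str], tuple[str, str]]]


def _pair_up(alleles: list[str], n_founders: int) -> list[tuple[str, str]]:
    """Assign alleles to ``n_founders`` slots of <=2 distinct each,
    reusing alleles so every founder is heteroallelic when possible."""
    alleles = sorted(alleles)
    pairs: list[tuple[str, str]] = []
    i = 0
    for _ in range(n_founders):
        if i + 1 < len(alleles):
            pairs.append((alleles[i], alleles[i + 1]))
            i += 2
        elif i < len(alleles):
            # one allele left: pair it with an already-covered one
            other = alleles[0] if alleles[0] != alleles[i] else alleles[i]
            pairs.append(tuple(sorted((alleles[i], other))))
            i += 1
        else:
            pairs.append((alleles[0], alleles[1] if len(alleles) > 1 else alleles[0]))
    return pairs


def minimal_founders(
    a_alleles: set[str], b_alleles: set[str]
) -> FounderSolution:
    """Fewest founding dikaryons that jointly carry all observed alleles.

    Each dikaryon holds two nuclei, hence at most two distinct alleles
    per locus, so n founders cover at most 2n alleles per locus and the
    minimum is ``max(ceil(nA/2), ceil(nB/2))``. Returns one witness
    assignment.
    """
    if not a_alleles or not b_alleles:
        raise ValueError("need at least one allele per locus")
    n_a, n_b = len(a_alleles), len(b_alleles)
    n = max((n_a + 1) // 2, (n_b + 1) // 2, 1)
    a_pairs = _pair_up(sorted(a_alleles), n)
    b_pairs = _pair_up(sorted(b_alleles), n)
    return FounderSolution(
        n_dikaryons=n, assignments=list(zip(a_pairs, b_pairs))
    )


def founders_cover(
    solution: FounderSolution, a_alleles: set[str], b_alleles: set[str]
) -> bool:
    """Check a founder assignment is valid and covers every allele."""
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a_pair, b_pair in solution.assignments:
        if len(a_pair) != 2 or len(b_pair) != 2:
            return False
        seen_a |= set(a_pair)
        seen_b |= set(b_pair)
    return seen_a >= a_alleles and seen_b >= b_alleles


@dataclass
class ResolutionAudit:
    """Marker-resolution audit against functional mating factors.

    ``mapping`` gives, per locus, the functional->proxy label map.
    A proxy hit by k > 1 functional factors cannot distinguish them;
    the k-1 minority factors (most-frequent kept, ties lexicographic)
    are reported as unresolved. A functional factor observed with two
    different proxies is an inconsistency, reported separately.
    """

    mapping: dict[Locus, dict[str, str]]
    unresolved: dict[Locus, list[str]]
    inconsistent: dict[Locus, list[str]]
    n_functional: dict[Locus, int]
    n_skipped: int

    @property
    def n_unresolved(self) -> int:
        return sum(len(v) for v in self.unresolved.values())


def marker_resolution_audit(
    pairs: list[FunctionalProxyPair],
) -> ResolutionAudit:
    """Audit how well marker proxies resolve functional mating factors."""
    n_skipped = 0
    per_locus_obs: dict[Locus, list[tuple[str, str]]] = {
        Locus.MAT_A: [],
        Locus.MAT_B: [],
    }
    for pair in pairs:
        if not all(
            (pair.functional_a, pair.functional_b, pair.proxy_a, pair.proxy_b)
        ):
            warnings.warn(f"{pair.strain_id}: missing labels; strain skipped")
            n_skipped += 1
            continue
        per_locus_obs[Locus.MAT_A].append((pair.functional_a, pair.proxy_a))
        per_locus_obs[Locus.MAT_B].append((pair.functional_b, pair.proxy_b))

    mapping: dict[Locus, dict[str, str]] = {}
    unresolved: dict[Locus, list[str]] = {}
    inconsistent: dict[Locus, list[str]] = {}
    n_functional: dict[Locus, int] = {}
    for locus, obs in per_locus_obs.items():
        func_to_proxies: dict[str, set[str]] = defaultdict(set)
        func_counts: Counter = Counter()
        for func, proxy in obs:
            func_to_proxies[func].add(proxy)
            func_counts[func] += 1
        n_functional[locus] = len(func_to_proxies)
        inconsistent[locus] = sorted(
            f for f, proxies in func_to_proxies.items() if len(proxies) > 1
        )
        loc_map = {
            f: next(iter(proxies))
            for f, proxies in func_to_proxies.items()
            if len(proxies) == 1
        }
        mapping[locus] = dict(sorted(loc_map.items()))
        proxy_to_funcs: dict[str, list[str]] = defaultdict(list)
        for f, proxy in loc_map.items():
            proxy_to_funcs[proxy].append(f)
        lost: list[str] = []
        for funcs in proxy_to_funcs.values():
            if len(funcs) > 1:
                funcs = sorted(funcs, key=lambda f: (-func_counts[f], f))
                lost.extend(funcs[1:])
        unresolved[locus] = sorted(lost)
    return ResolutionAudit(
        mapping=mapping,
        unresolved=unresolved,
        inconsistent=inconsistent,
        n_functional=n_functional,
        n_skipped=n_skipped,
    )


def single_allele_strain_counts(
    table: PopulationTable,
) -> dict[str, dict[Locus, int]]:
    """Count dikaryons observed with one allele at a locus, under two
    conventions for strains whose *other* locus is entirely blank.

    ``all_single`` counts every dikaryon flagged single at the locus;
    ``other_locus_observed`` additionally requires some data at the
    other locus. Both are reported because a blank companion locus makes
    the single-allele call ambiguous (failed amplification vs genuinely
    unsampled second allele).
    """
    out = {
        "all_single": {Locus.MAT_A: 0, Locus.MAT_B: 0},
        "other_locus_observed": {Locus.MAT_A: 0, Locus.MAT_B: 0},
    }
    flag_for = {Locus.MAT_A: GenotypeFlag.A_SINGLE, Locus.MAT_B: GenotypeFlag.B_SINGLE}
    other = {Locus.MAT_A: Locus.MAT_B, Locus.MAT_B: Locus.MAT_A}
    for entry in table:
        if entry.ploidy is not Ploidy.dikaryon:
            continue
        for locus in Locus:
            if flag_for[locus] in entry.flags:
                out["all_single"][locus] += 1
                if entry.alleles(other[locus]):
                    out["other_locus_observed"][locus] += 1
    return out


def exhaustive_minimal_founders(
    a_alleles: set[str], b_alleles: set[str], max_n: int = 6
) -> int:
    """Brute-force oracle: smallest n for which some assignment of
    allele pairs to n dikaryons covers every allele at both loci.

    Enumerates all combinations of unordered allele pairs per locus;
    intended for small allele sets (nA, nB <= 2*max_n).
    """
    if not a_alleles or not b_alleles:
        raise ValueError("need at least one allele per locus")

    def coverable(alleles: set[str], n: int) -> bool:
        opts = list(
            itertools.combinations_with_replacement(sorted(alleles), 2)
        )
        for combo in itertools.combinations_with_replacement(opts, n):
            if set().union(*(set(p) for p in combo)) >= alleles:
                return True
        return False

    for n in range(1, max_n + 1):
        if coverable(a_alleles, n) and coverable(b_alleles, n):
            return n
    raise RuntimeError(f"no cover found with up to {max_n} founders")
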