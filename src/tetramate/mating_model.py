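"""Tetrapolar mating-compatibility model.

In a tetrapolar basidiomycete two monokaryons mate successfully only if
they carry different alleles at *both* mating loci (MAT A and MAT B).
This module implements that rule and everything built directly on it:
predicted pairwise crossing matrices, concordance scoring of predictions
against observed crossing results, enumeration of the four progeny
genotype classes of a dikaryon, the sib-compatibility fraction, and
inference of compatibility classes (and mating-system polarity) from a
crossing matrix alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .types import CrossOutcome, Locus, MatingGenotype, Ploidy


def _pair_key(id1: str, id2: str) -> tuple[str, str]:
    return (id1, id2) if id1 <= id2 else (id2, id1)


@dataclass
class CrossingMatrix:
    """Symmetric pairwise mating-outcome table over monokaryon ids.

    ``outcomes`` maps unordered id pairs (stored sorted) to a
    :class:`CrossOutcome`. Absent pairs mean the cross was not
    performed. Self pairs follow ``diagonal_policy``:
    ``self_incompatible`` records the diagonal as incompatible,
    ``self_excluded`` leaves it out entirely.
    """

    ids: list[str]
    outcomes: dict[tuple[str, str], CrossOutcome] = field(default_factory=dict)
    diagonal_policy: str = "self_excluded"

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in crossing matrix")
        if self.diagonal_policy not in ("self_incompatible", "self_excluded"):
            raise ValueError(f"unknown diagonal_policy {self.diagonal_policy}")
        known = set(self.ids)
        for i, j in self.outcomes:
            if i not in known or j not in known:
                raise ValueError(f"outcome for unknown id pair ({i}, {j})")

    def set(self, id1: str, id2: str, outcome: CrossOutcome) -> None:
        self.outcomes[_pair_key(id1, id2)] = outcome

    def get(self, id1: str, id2: str) -> CrossOutcome | None:
        return self.outcomes.get(_pair_key(id1, id2))

    def pairs(self, include_diagonal: bool = False):
        """Unordered id pairs in canonical order (matrix id order)."""
        for i, a in enumerate(self.ids):
            for b in self.ids[i if include_diagonal else i + 1:]:
                yield (a, b)

    def n_unresolved(self) -> int:
        return sum(
            1 for v in self.outcomes.values() if v is CrossOutcome.unresolved
        )


@dataclass
class ConcordanceReport:
    """Agreement between a predicted and an observed crossing matrix.

    Pairs observed as unresolved are excluded from scoring, so
    ``n_pairs_scored == n_match + n_mismatch``.
    """

    n_pairs_scored: int
    n_match: int
    n_mismatch: int
    n_unresolved: int
    mismatches: list[tuple[str, str, CrossOutcome, CrossOutcome]]

    @property
    def fully_concordant(self) -> bool:
        return self.n_mismatch == 0


def _require_complete(genotype: MatingGenotype) -> None:
    if genotype.ploidy is not Ploidy.monokaryon:
        raise ValueError(f"{genotype.strain_id}: not a monokaryon")
    if len(genotype.a_alleles) != 1 or len(genotype.b_alleles) != 1:
        raise ValueError(
            f"{genotype.strain_id}: incomplete genotype "
            f"(A={sorted(genotype.a_alleles)}, B={sorted(genotype.b_alleles)}); "
            "filter incomplete genotypes before compatibility calls"
        )


def is_compatible(g1: MatingGenotype, g2: MatingGenotype) -> CrossOutcome:
    """Tetrapolar compatibility of two complete monokaryon genotypes.

    Compatible iff the two strains differ at MAT A *and* at MAT B; a
    self-cross (or any pair sharing either locus) is incompatible.
    Never returns ``unresolved``.
    """
    _require_complete(g1)
    _require_complete(g2)
    if (
        g1.single_allele(Locus.MAT_A) != g2.single_allele(Locus.MAT_A)
        and g1.single_allele(Locus.MAT_B) != g2.single_allele(Locus.MAT_B)
    ):
        return CrossOutcome.compatible
    return CrossOutcome.incompatible


def predict_matrix(
    genotypes: list[MatingGenotype],
    diagonal_policy: str = "self_incompatible",
) -> CrossingMatrix:
    """Predict every pairwise crossing outcome from genotypes alone."""
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    ids = [g.strain_id for g in genotypes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate strain ids")
    for g in genotypes:
        _require_complete(g)
    matrix = CrossingMatrix(ids=list(ids), diagonal_policy=diagonal_policy)
    for g1, g2 in itertools.combinations(genotypes, 2):
        matrix.set(g1.strain_id, g2.strain_id, is_compatible(g1, g2))
    if diagonal_policy == "self_incompatible":
        for g in genotypes:
            matrix.set(g.strain_id, g.strain_id, CrossOutcome.incompatible)
    return matrix


def compare_matrices(
    predicted: CrossingMatrix,
    observed: CrossingMatrix,
    include_diagonal: bool = False,
) -> ConcordanceReport:
    """Score a predicted matrix against observed crossing results.

    Observed-unresolved pairs count toward ``n_unresolved`` and are not
    scored; pairs absent from the observed matrix (cross not performed)
    are skipped entirely. The diagonal is excluded by default.
    """
    if set(predicted.ids) != set(observed.ids):
        only_pred = sorted(set(predicted.ids) - set(observed.ids))
        only_obs = sorted(set(observed.ids) - set(predicted.ids))
        raise ValueError(
            f"id sets differ: only in predicted {only_pred}, "
            f"only in observed {only_obs}"
        )
    n_match = n_mismatch = n_unresolved = 0
    mismatches: list[tuple[str, str, CrossOutcome, CrossOutcome]] = []
    for a, b in observed.pairs(include_diagonal=include_diagonal):
        obs = observed.get(a, b)
        if obs is None:
            continue
        if obs is CrossOutcome.unresolved:
            n_unresolved += 1
            continue
        pred = predicted.get(a, b)
        if pred is None:
            raise ValueError(f"predicted matrix lacks pair ({a}, {b})")
        if pred is obs:
            n_match += 1
        else:
            n_mismatch += 1
            mismatches.append((a, b, pred, obs))
    return ConcordanceReport(
        n_pairs_scored=n_match + n_mismatch,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_unresolved=n_unresolved,
        mismatches=mismatches,
    )


def _require_doubly_heteroallelic(parent: MatingGenotype) -> None:
    if parent.ploidy is not Ploidy.dikaryon:
        raise ValueError(f"{parent.strain_id}: not a dikaryon")
    if len(parent.a_alleles) != 2 or len(parent.b_alleles) != 2:
        raise ValueError(
            f"{parent.strain_id}: parent must carry exactly 2 alleles per "
            f"locus (A={sorted(parent.a_alleles)}, "
            f"B={sorted(parent.b_alleles)})"
        )


def expected_progeny_classes(parent: MatingGenotype) -> list[MatingGenotype]:
    """The four monokaryon genotype classes a doubly heteroallelic
    dikaryon segregates: the Cartesian product of its allele pairs."""
    _require_doubly_heteroallelic(parent)
    classes = []
    for a in sorted(parent.a_alleles):
        for b in sorted(parent.b_alleles):
            classes.append(
                MatingGenotype.make(f"{a}{b}", Ploidy.monokaryon, {a}, {b})
            )
    return classes


def sib_compatibility_fraction(
    parent: MatingGenotype, loci: tuple[Locus, ...] = (Locus.MAT_A, Locus.MAT_B)
) -> float:
    """Probability that two independent random progeny are compatible.

    Progeny classes are equifrequent under fair segregation. For the
    tetrapolar rule this is exactly 1/4; restricting ``loci`` to a
    single locus models a hypothetical bipolar reduction (1/2).
    """
    classes = expected_progeny_classes(parent)
    compatible = 0
    total = 0
    for g1 in classes:
        for g2 in classes:
            total += 1
            if all(
                g1.single_allele(locus) != g2.single_allele(locus)
                for locus in loci
            ):
                compatible += 1
    return compatible / total


@dataclass
class CompatibilityClasses:
    """Partition of monokaryons by identical compatibility behaviour,
    plus the mating-system polarity the partition implies."""

    classes: list[list[str]]
    polarity: str  # tetrapolar | bipolar | undetermined
    compatible_fraction: float | None


def infer_compatibility_classes(
    observed: CrossingMatrix, tolerance: float = 0.10
) -> CompatibilityClasses:
    """Group sib monokaryons by compatibility profile and call polarity.

    Two ids share a class when their outcome rows agree at every pair
    where both are resolved (unresolved cells are wildcards). Polarity
    is tetrapolar when 4 classes emerge with a compatible-pair fraction
    within ``tolerance`` of 1/4, bipolar when 2 classes sit near 1/2,
    otherwise undetermined. Fewer than 4 ids is undetermined, not an
    error.
    """
    ids = sorted(observed.ids)
    if len(ids) < 4:
        return CompatibilityClasses([list(ids)], "undetermined", None)

    def profiles_match(a: str, b: str) -> bool:
        for other in ids:
            if other in (a, b):
                continue
            oa = observed.get(a, other)
            ob = observed.get(b, other)
            if oa is None or ob is None:
                continue
            if CrossOutcome.unresolved in (oa, ob):
                continue
            if oa is not ob:
                return False
        # same-class sibs never mate with each other
        mutual = observed.get(a, b)
        if mutual is CrossOutcome.compatible:
            return False
        return True

    classes: list[list[str]] = []
    for strain in ids:
        for group in classes:
            if all(profiles_match(strain, member) for member in group):
                group.append(strain)
                break
        else:
            classes.append([strain])

    resolved = [
        observed.get(a, b)
        for a, b in observed.pairs()
        if observed.get(a, b) in (CrossOutcome.compatible, CrossOutcome.incompatible)
    ]
    if not resolved:
        return CompatibilityClasses(classes, "undetermined", None)
    frac = sum(1 for o in resolved if o is CrossOutcome.compatible) / len(resolved)

    polarity = "undetermined"
    if len(classes) == 4 and abs(frac - 0.25) <= tolerance:
        polarity = "tetrapolar"
    elif len(classes) == 2 and abs(frac - 0.5) <= tolerance:
        polarity = "bipolar"
    return CompatibilityClasses(classes, polarity, frac)
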