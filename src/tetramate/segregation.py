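"""Spore-family segregation statistics.

A doubly heteroallelic dikaryon segregates its MAT alleles into four
progeny genotype classes. Under fair meiosis and unlinked loci the
classes are equifrequent; these functions count observed classes, test
goodness-of-fit to an expected ratio with a Pearson chi-square, and test
independence of the two loci (linkage) with a 2x2 contingency test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mating_model import expected_progeny_classes
from .types import Locus, MatingGenotype, SporeFamily


def _class_key(genotype: MatingGenotype) -> tuple[str, str]:
    return (
        genotype.single_allele(Locus.MAT_A),
        genotype.single_allele(Locus.MAT_B),
    )


@dataclass
class SegregationResult:
    class_counts: dict[tuple[str, str], int]
    chi2: float
    df: int
    p_value: float
    missing_classes: frozenset[tuple[str, str]]


def count_classes(
    family: SporeFamily,
) -> tuple[dict[tuple[str, str], int], frozenset[tuple[str, str]]]:
    """Count progeny per expected genotype class.

    Expected classes come from the parent genotype (Cartesian product of
    its allele pairs), not from the observed progeny, so classes absent
    from the progeny are reported with count 0 and listed as missing.
    A progeny allele not carried by the parent is rejected at
    :class:`SporeFamily` construction.
    """
    expected = [_class_key(g) for g in expected_progeny_classes(family.parent)]
    counts = {key: 0 for key in expected}
    for child in family.progeny:
        key = _class_key(child)
        counts[key] += 1  # key membership guaranteed by SporeFamily invariant
    missing = frozenset(key for key, n in counts.items() if n == 0)
    return counts, missing


def segregation_gof(
    class_counts: dict,
    expected_ratio: list[float] | None = None,
) -> SegregationResult:
    """Pearson chi-square goodness-of-fit of class counts to a ratio.

    ``expected_ratio`` defaults to uniform (1:1:1:1 for four classes);
    it is normalised internally. df = number of classes - 1. No
    continuity correction is applied.
    """
    keys = list(class_counts.keys())
    observed = np.asarray([class_counts[k] for k in keys], dtype=float)
    if len(keys) < 2:
        raise ValueError("need at least two classes")
    total = observed.sum()
    if total <= 0:
        raise ValueError("zero total count")
    if expected_ratio is None:
        weights = np.ones(len(keys))
    else:
        weights = np.asarray(expected_ratio, dtype=float)
        if len(weights) != len(keys):
            raise ValueError("expected_ratio length mismatch")
        if np.any(weights <= 0):
            raise ValueError("expected_ratio weights must be positive")
    expected = total * weights / weights.sum()
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = len(keys) - 1
    p = float(stats.chi2.sf(chi2, df))
    missing = frozenset(k for k, n in class_counts.items() if n == 0)
    return SegregationResult(
        class_counts=dict(class_counts),
        chi2=chi2,
        df=df,
        p_value=p,
        missing_classes=missing,
    )


@dataclass
class IndependenceResult:
    """2x2 contingency of parental MAT A allele x MAT B allele among
    progeny, with a chi-square (or exact) test of locus independence."""

    table: np.ndarray
    a_alleles: tuple[str, str]
    b_alleles: tuple[str, str]
    statistic: float
    p_value: float
    method: str
    recombination_fraction: float


def locus_independence(
    family: SporeFamily,
    yates: bool = False,
    exact: bool = False,
) -> IndependenceResult:
    """Test independence of MAT A and MAT B segregation in a family.

    Builds the 2x2 table of parental A allele by parental B allele over
    the progeny and applies a Pearson chi-square (Yates correction
    optional, default off) or Fisher's exact test. Also reports the
    estimated recombination fraction: the proportion of progeny in the
    two minority (putative recombinant) diagonal classes, 0.5 meaning
    free recombination.
    """
    counts, _ = count_classes(family)
    a_alleles = tuple(sorted(family.parent.a_alleles))
    b_alleles = tuple(sorted(family.parent.b_alleles))
    table = np.array(
        [
            [counts[(a, b)] for b in b_alleles]
            for a in a_alleles
        ],
        dtype=float,
    )
    n = table.sum()
    if n <= 0:
        raise ValueError("empty family")

    if exact:
        _, p = stats.fisher_exact(table)
        stat = float("nan")
        method = "fisher_exact"
    else:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        if np.any(expected == 0):
            stat, p = 0.0, 1.0
        else:
            diff = np.abs(table - expected)
            if yates:
                diff = np.maximum(diff - 0.5, 0.0)
            stat = float(np.sum(diff**2 / expected))
            p = float(stats.chi2.sf(stat, 1))
        method = "chi2_yates" if yates else "chi2"

    # the rarer diagonal holds the recombinant classes
    diag = table[0, 0] + table[1, 1]
    anti = table[0, 1] + table[1, 0]
    r_hat = min(diag, anti) / n
    return IndependenceResult(
        table=table,
        a_alleles=a_alleles,
        b_alleles=b_alleles,
        statistic=stat,
        p_value=p,
        method=method,
        recombination_fraction=r_hat,
    )
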