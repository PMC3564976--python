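"""Domain types shared across the package.

The vocabulary follows standard basidiomycete mating-system usage: a
*monokaryon* is a haploid mycelium carrying one allele per mating locus;
a *dikaryon* carries two genetically distinct nuclei and is heteroallelic
at both MAT loci. ``MAT_A`` is the homeodomain locus, ``MAT_B`` the
pheromone/receptor locus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")


class Locus(str, enum.Enum):
    MAT_A = "MAT_A"
    MAT_B = "MAT_B"


class Source(str, enum.Enum):
    """How a marker sequence was obtained.

    Monokaryons are sequenced directly from the amplicon; dikaryon
    amplicons are cloned first, so each read reports one of the two
    alleles.
    """

    direct = "direct"
    clone = "clone"


class Ploidy(str, enum.Enum):
    monokaryon = "monokaryon"
    dikaryon = "dikaryon"


class GenotypeFlag(str, enum.Enum):
    A_MISSING = "A_MISSING"
    B_MISSING = "B_MISSING"
    A_SINGLE = "A_SINGLE"
    B_SINGLE = "B_SINGLE"
    A_EXCESS = "A_EXCESS"
    B_EXCESS = "B_EXCESS"


class CrossOutcome(str, enum.Enum):
    """Outcome of a pairwise mating test.

    ``compatible`` means clamp connections (dikaryon formation) were
    observed or predicted; ``unresolved`` is only legal for observed
    matrices (a prediction on complete genotypes is always decided).
    """

    compatible = "compatible"
    incompatible = "incompatible"
    unresolved = "unresolved"


@dataclass(frozen=True)
class MarkerSequence:
    """One sequenced read of a MAT-linked marker for one strain."""

    strain_id: str
    locus: Locus
    sequence: str
    source: Source
    clone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.strain_id}: empty sequence")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.strain_id}: invalid DNA characters {sorted(bad)}"
            )
        if (self.source is Source.clone) != (self.clone_id is not None):
            raise ValueError(
                f"{self.strain_id}: clone_id must be present iff source=clone"
            )


@dataclass
class AlleleCatalog:
    """Named alleles for one locus: label -> representative sequence.

    ``alleles`` preserves label order (largest cluster first by
    convention of the clustering step).
    """

    locus: Locus
    alleles: list[tuple[str, str]]

    def labels(self) -> list[str]:
        return [label for label, _ in self.alleles]

    def representative(self, label: str) -> str:
        for lab, seq in self.alleles:
            if lab == label:
                return seq
        raise KeyError(label)

    def __post_init__(self) -> None:
        labels = self.labels()
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate allele labels at {self.locus.value}")


@dataclass
class MatingGenotype:
    """Per-strain allele content at the two MAT loci.

    For dikaryons the sets record what was *observed*; a single observed
    allele is flagged ``A_SINGLE``/``B_SINGLE`` and never promoted to a
    homoallelic call, because dikaryons are heteroallelic at both loci by
    the mating model. Empty sets carry the ``*_MISSING`` flag.
    """

    strain_id: str
    ploidy: Ploidy
    a_alleles: frozenset[str]
    b_alleles: frozenset[str]
    flags: frozenset[GenotypeFlag] = field(default_factory=frozenset)
    country: Optional[str] = None
    locality: Optional[str] = None

    @staticmethod
    def derive_flags(
        ploidy: Ploidy, a_alleles: frozenset[str], b_alleles: frozenset[str]
    ) -> frozenset[GenotypeFlag]:
        flags: set[GenotypeFlag] = set()
        if not a_alleles:
            flags.add(GenotypeFlag.A_MISSING)
        if not b_alleles:
            flags.add(GenotypeFlag.B_MISSING)
        if ploidy is Ploidy.dikaryon:
            if len(a_alleles) == 1:
                flags.add(GenotypeFlag.A_SINGLE)
            elif len(a_alleles) > 2:
                flags.add(GenotypeFlag.A_EXCESS)
            if len(b_alleles) == 1:
                flags.add(GenotypeFlag.B_SINGLE)
            elif len(b_alleles) > 2:
                flags.add(GenotypeFlag.B_EXCESS)
        return frozenset(flags)

    @classmethod
    def make(
        cls,
        strain_id: str,
        ploidy: Ploidy,
        a_alleles,
        b_alleles,
        country: Optional[str] = None,
        locality: Optional[str] = None,
    ) -> "MatingGenotype":
        """Build a genotype with flags derived from the allele sets."""
        a = frozenset(a_alleles)
        b = frozenset(b_alleles)
        if ploidy is Ploidy.monokaryon and (len(a) > 1 or len(b) > 1):
            raise ValueError(
                f"{strain_id}: monokaryon with multiple alleles at a locus "
                f"(A={sorted(a)}, B={sorted(b)}); contamination or "
                "mislabeled ploidy"
            )
        return cls(
            strain_id=strain_id,
            ploidy=ploidy,
            a_alleles=a,
            b_alleles=b,
            flags=cls.derive_flags(ploidy, a, b),
            country=country,
            locality=locality,
        )

    def alleles(self, locus: Locus) -> frozenset[str]:
        return self.a_alleles if locus is Locus.MAT_A else self.b_alleles

    @property
    def is_complete_monokaryon(self) -> bool:
        return (
            self.ploidy is Ploidy.monokaryon
            and len(self.a_alleles) == 1
            and len(self.b_alleles) == 1
        )

    def single_allele(self, locus: Locus) -> str:
        alleles = self.alleles(locus)
        if len(alleles) != 1:
            raise ValueError(
                f"{self.strain_id}: expected one allele at {locus.value}, "
                f"found {sorted(alleles)}"
            )
        return next(iter(alleles))


@dataclass
class PopulationTable:
    """Ordered collection of strain genotypes with unique ids."""

    entries: list[MatingGenotype]

    def __post_init__(self) -> None:
        ids = [e.strain_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate strain ids: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, strain_id: str) -> MatingGenotype:
        for e in self.entries:
            if e.strain_id == strain_id:
                return e
        raise KeyError(strain_id)


@dataclass(frozen=True)
class FunctionalProxyPair:
    """Functional mating factors (from crossing studies) paired with the
    marker-based proxy genotype of the same monokaryon."""

    strain_id: str
    functional_a: str
    functional_b: str
    proxy_a: str
    proxy_b: str


@dataclass
class SporeFamily:
    """A dikaryotic parent and the monokaryotic progeny isolated from
    basidiospores of its fruit body."""

    parent: MatingGenotype
    progeny: list[MatingGenotype]

    def __post_init__(self) -> None:
        if self.parent.ploidy is not Ploidy.dikaryon:
            raise ValueError("parent must be a dikaryon")
        for child in self.progeny:
            for locus in Locus:
                extra = child.alleles(locus) - self.parent.alleles(locus)
                if extra:
                    raise ValueError(
                        f"progeny {child.strain_id} carries {sorted(extra)} "
                        f"at {locus.value} not present in parent "
                        f"{self.parent.strain_id}"
                    )


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame located on a DNA source sequence.

    Coordinates are 0-based half-open on the forward strand; ``protein``
    excludes the stop codon.
    """

    source_id: str
    strand: str
    start: int
    end: int
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span not a multiple of 3")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with coordinates")


@dataclass(frozen=True)
class PheromoneCandidate:
    """A small ORF or protein ending in a CaaX prenylation motif."""

    source_id: str
    protein: str
    caax: str
    length_aa: int
    strand: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    score_notes: tuple[str, ...] = ()
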