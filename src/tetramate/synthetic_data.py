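"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can be exercised without real sequence
data: allele representative sequences diverged from a common ancestor,
a population of mono- and dikaryotic strains with cloned marker reads
and allele dropout, four-class Mendelian spore families with optional
segregation distortion and linkage, crossing matrices with scoring
error and unresolved cells, and a Wright-Fisher simulator of mating-type
allele dynamics through a population bottleneck.

The Wright-Fisher model implements negative frequency-dependent
selection implicitly: parent pairs are drawn uniformly and rejected
unless they differ at both MAT loci, so carriers of rare mating-type
alleles are accepted into more pairings. A neutral locus segregates
alongside the MAT loci as the drift control.

Defaults mirror the sampling design of the European dry-rot study the
package analyses: 26 dikaryotic strains, 3 MAT A and 4 MAT B alleles,
8 clones sequenced per dikaryon marker, spore families of 23, unlinked
loci (r = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mating_model import (
    CrossingMatrix,
    expected_progeny_classes,
    is_compatible,
)
from .types import (
    AlleleCatalog,
    CrossOutcome,
    Locus,
    MarkerSequence,
    MatingGenotype,
    Ploidy,
    PopulationTable,
    Source,
    SporeFamily,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic sampling design."""

    seed: int = 0
    n_alleles_a: int = 3
    n_alleles_b: int = 4
    allele_freqs_a: Optional[list[float]] = None
    allele_freqs_b: Optional[list[float]] = None
    marker_len: int = 500
    inter_allele_divergence: float = 0.05
    n_strains: int = 26
    prop_monokaryon: float = 0.0
    clones_per_marker: int = 8
    clone_dropout: float = 0.1
    seq_error_rate: float = 0.0
    family_size: int = 23
    distortion: Optional[list[float]] = None
    recomb_fraction: float = 0.5
    cross_error: float = 0.0
    cross_unresolved: float = 1 / 120

    def __post_init__(self) -> None:
        for name in ("prop_monokaryon", "clone_dropout", "seq_error_rate",
                     "recomb_fraction", "cross_error", "cross_unresolved"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("allele_freqs_a", "allele_freqs_b"):
            freqs = getattr(self, name)
            if freqs is not None and abs(sum(freqs) - 1.0) > 1e-8:
                raise ValueError(f"{name} must sum to 1")
        if self.distortion is not None and any(w <= 0 for w in self.distortion):
            raise ValueError("distortion weights must be positive")


def _locus_labels(locus: Locus, n: int) -> list[str]:
    prefix = "A" if locus is Locus.MAT_A else "B"
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with the given probability,
    always to a different base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def make_allele_sequences(cfg: SimConfig) -> dict[Locus, AlleleCatalog]:
    """Representative marker sequences per allele per locus.

    A random ancestral sequence is drawn per locus; the first allele is
    the ancestor and the rest carry independent substitutions at the
    configured divergence. Colliding alleles are resampled so pairwise
    divergence is always > 0. Deterministic for a fixed seed.
    """
    if cfg.marker_len < 50:
        raise ValueError("marker_len must be >= 50")
    n_per_locus = {Locus.MAT_A: cfg.n_alleles_a, Locus.MAT_B: cfg.n_alleles_b}
    if cfg.inter_allele_divergence == 0 and any(
        n > 1 for n in n_per_locus.values()
    ):
        raise ValueError("divergence 0 cannot yield more than one allele")
    rng = np.random.default_rng(cfg.seed)
    catalogs: dict[Locus, AlleleCatalog] = {}
    for locus in Locus:
        n = n_per_locus[locus]
        if n < 1:
            raise ValueError(f"need at least one allele at {locus.value}")
        ancestor = rng.choice(_BASES, size=cfg.marker_len)
        seqs = ["".join(ancestor)]
        while len(seqs) < n:
            cand = "".join(_mutate(ancestor, cfg.inter_allele_divergence, rng))
            if cand not in seqs:
                seqs.append(cand)
        catalogs[locus] = AlleleCatalog(
            locus=locus,
            alleles=list(zip(_locus_labels(locus, n), seqs)),
        )
    return catalogs


def _freqs(cfg: SimConfig, locus: Locus) -> np.ndarray:
    if locus is Locus.MAT_A:
        given, n = cfg.allele_freqs_a, cfg.n_alleles_a
    else:
        given, n = cfg.allele_freqs_b, cfg.n_alleles_b
    if given is not None:
        if len(given) != n:
            raise ValueError(f"{locus.value}: frequency vector length != allele count")
        return np.asarray(given, dtype=float)
    return np.full(n, 1.0 / n)


def _draw_distinct_pair(
    labels: list[str], freqs: np.ndarray, rng: np.random.Generator
) -> tuple[str, str]:
    first = rng.choice(len(labels), p=freqs)
    rest = freqs.copy()
    rest[first] = 0.0
    rest /= rest.sum()
    second = rng.choice(len(labels), p=rest)
    return labels[first], labels[second]


def simulate_population(
    cfg: SimConfig,
) -> tuple[PopulationTable, list[MarkerSequence], dict[Locus, AlleleCatalog]]:
    """A strain population plus the marker reads it would yield.

    Monokaryon alleles are drawn from the allele frequencies; dikaryons
    are formed as compatible nucleus pairs (alleles differ at both
    loci). Each monokaryon locus yields one direct read; each dikaryon
    locus yields ``clones_per_marker`` clone reads, where a clone picks
    one of the two alleles uniformly and the read is lost with
    probability ``clone_dropout`` — the mechanism behind dikaryons
    observed with a single allele. Returns the truth genotype table,
    the observed reads, and the allele catalogs used.
    """
    rng = np.random.default_rng(cfg.seed)
    catalogs = make_allele_sequences(cfg)
    labels = {locus: catalogs[locus].labels() for locus in Locus}
    seq_of = {
        locus: dict(catalogs[locus].alleles) for locus in Locus
    }
    if cfg.prop_monokaryon < 1.0:
        for locus in Locus:
            if len(labels[locus]) < 2 or np.count_nonzero(_freqs(cfg, locus)) < 2:
                raise ValueError(
                    f"{locus.value}: heteroallelic dikaryons need >= 2 "
                    "alleles with positive frequency"
                )

    entries: list[MatingGenotype] = []
    reads: list[MarkerSequence] = []
    for i in range(cfg.n_strains):
        strain = f"sim{i + 1:03d}"
        is_mono = rng.random() < cfg.prop_monokaryon
        per_locus: dict[Locus, tuple[str, ...]] = {}
        for locus in Locus:
            freqs = _freqs(cfg, locus)
            if is_mono:
                allele = labels[locus][rng.choice(len(freqs), p=freqs)]
                per_locus[locus] = (allele,)
            else:
                per_locus[locus] = _draw_distinct_pair(labels[locus], freqs, rng)
        entries.append(
            MatingGenotype.make(
                strain,
                Ploidy.monokaryon if is_mono else Ploidy.dikaryon,
                set(per_locus[Locus.MAT_A]),
                set(per_locus[Locus.MAT_B]),
            )
        )
        for locus in Locus:
            if is_mono:
                seq = _read_sequence(
                    seq_of[locus][per_locus[locus][0]], cfg.seq_error_rate, rng
                )
                reads.append(
                    MarkerSequence(strain, locus, seq, Source.direct)
                )
            else:
                pair = per_locus[locus]
                for c in range(cfg.clones_per_marker):
                    allele = pair[rng.integers(2)]
                    if rng.random() < cfg.clone_dropout:
                        continue
                    seq = _read_sequence(
                        seq_of[locus][allele], cfg.seq_error_rate, rng
                    )
                    reads.append(
                        MarkerSequence(
                            strain, locus, seq, Source.clone, clone_id=f"c{c + 1}"
                        )
                    )
    return PopulationTable(entries), reads, catalogs


def _read_sequence(
    true_seq: str, error_rate: float, rng: np.random.Generator
) -> str:
    if error_rate <= 0:
        return true_seq
    return "".join(_mutate(np.array(list(true_seq)), error_rate, rng))


def simulate_spore_family(parent: MatingGenotype, cfg: SimConfig) -> SporeFamily:
    """Progeny of a doubly heteroallelic dikaryon.

    The four genotype classes are the Cartesian product of the parent's
    allele pairs. The parental nuclear combinations are taken to be
    (a1, b1) and (a2, b2) in sorted-label order; those classes carry
    probability (1 - r)/2 each and the recombinant classes r/2, with
    r = ``recomb_fraction`` (0.5 = unlinked). Optional ``distortion``
    weights multiply the class probabilities before normalisation.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = expected_progeny_classes(parent)  # sorted a x sorted b
    a_sorted = sorted(parent.a_alleles)
    b_sorted = sorted(parent.b_alleles)
    parental = {
        (a_sorted[0], b_sorted[0]),
        (a_sorted[1], b_sorted[1]),
    }
    r = cfg.recomb_fraction
    probs = np.array(
        [
            (1 - r) / 2
            if (
                next(iter(g.a_alleles)),
                next(iter(g.b_alleles)),
            )
            in parental
            else r / 2
            for g in classes
        ]
    )
    if cfg.distortion is not None:
        if len(cfg.distortion) != len(classes):
            raise ValueError("distortion must give one weight per class")
        probs = probs * np.asarray(cfg.distortion, dtype=float)
    if probs.sum() <= 0:
        raise ValueError("class probabilities sum to zero")
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=cfg.family_size, p=probs)
    progeny = [
        MatingGenotype.make(
            f"{parent.strain_id}_p{i + 1}",
            Ploidy.monokaryon,
            classes[k].a_alleles,
            classes[k].b_alleles,
        )
        for i, k in enumerate(draws)
    ]
    return SporeFamily(parent=parent, progeny=progeny)


def simulate_cross_matrix(
    genotypes: list[MatingGenotype],
    cross_error: float = 0.0,
    cross_unresolved: float = 0.0,
    seed: int = 0,
) -> CrossingMatrix:
    """Observed crossing matrix: truth from the compatibility rule, each
    cell flipped with probability ``cross_error`` and then set
    unresolved with probability ``cross_unresolved``. Symmetric by
    construction (one draw per unordered pair)."""
    rng = np.random.default_rng(seed)
    matrix = CrossingMatrix(ids=[g.strain_id for g in genotypes])
    for i, g1 in enumerate(genotypes):
        for g2 in genotypes[i + 1:]:
            outcome = is_compatible(g1, g2)
            if rng.random() < cross_error:
                outcome = (
                    CrossOutcome.incompatible
                    if outcome is CrossOutcome.compatible
                    else CrossOutcome.compatible
                )
            if rng.random() < cross_unresolved:
                outcome = CrossOutcome.unresolved
            matrix.set(g1.strain_id, g2.strain_id, outcome)
    return matrix


# ---------------------------------------------------------------------------
# Wright-Fisher simulator


@dataclass
class WrightFisherConfig:
    """A severe-bottleneck scenario with matched initial richness.

    ``pop_size`` haploid individuals carry one allele at each of MAT A,
    MAT B, and a neutral control locus. At ``bottleneck_gen`` the
    population is downsampled without replacement to
    ``bottleneck_size`` and recovers to ``pop_size`` the next
    generation. Mate choice is rejection sampling: pairs not differing
    at both MAT loci are redrawn, up to ``max_mate_retries`` per
    offspring, after which the pair is accepted anyway and counted as a
    failed mating.
    """

    seed: int = 0
    pop_size: int = 200
    bottleneck_size: int = 6
    bottleneck_gen: int = 20
    total_gens: int = 80
    n_mat_a: int = 3
    n_mat_b: int = 3
    n_neutral: int = 3
    max_mate_retries: int = 100

    def __post_init__(self) -> None:
        if self.bottleneck_size > self.pop_size:
            raise ValueError("bottleneck_size must be <= pop_size")
        if self.total_gens < 1:
            raise ValueError("total_gens must be positive")
        if self.n_mat_a < 2 or self.n_mat_b < 2:
            raise ValueError(
                "need >= 2 initial alleles at each MAT locus "
                "(no compatible pairs otherwise)"
            )


_WF_LOCI = ("MAT_A", "MAT_B", "neutral")


@dataclass
class WrightFisherResult:
    trajectories: pd.DataFrame  # generation, locus, allele, frequency
    richness: pd.DataFrame  # generation, locus, richness
    failed_matings: int
    final_richness: dict[str, int] = field(default_factory=dict)


def _init_population(n_alleles: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Equifrequent initial assignment, shuffled."""
    base = np.resize(np.arange(n_alleles), n)
    rng.shuffle(base)
    return base


def simulate_wright_fisher(cfg: WrightFisherConfig) -> WrightFisherResult:
    """Forward simulation of MAT and neutral allele trajectories.

    Each generation, every one of N offspring draws a parent pair
    uniformly with replacement, rejecting pairs that share an allele at
    either MAT locus; the offspring inherits one allele per locus
    independently from either parent. Rare MAT alleles are thereby
    favoured (their carriers are rejected less often) while the neutral
    locus experiences pure drift — an implicit model of negative
    frequency-dependent selection.
    """
    rng = np.random.default_rng(cfg.seed)
    n_init = {"MAT_A": cfg.n_mat_a, "MAT_B": cfg.n_mat_b, "neutral": cfg.n_neutral}
    pop = {
        locus: _init_population(n_init[locus], cfg.pop_size, rng)
        for locus in _WF_LOCI
    }
    failed = 0
    traj_rows: list[tuple[int, str, int, float]] = []
    rich_rows: list[tuple[int, str, int]] = []

    def record(gen: int) -> None:
        for locus in _WF_LOCI:
            values, counts = np.unique(pop[locus], return_counts=True)
            n = counts.sum()
            for allele, count in zip(values, counts):
                traj_rows.append((gen, locus, int(allele), count / n))
            rich_rows.append((gen, locus, len(values)))

    record(0)
    for gen in range(1, cfg.total_gens + 1):
        m = len(pop["MAT_A"])
        n_off = cfg.pop_size
        p1 = rng.integers(0, m, size=n_off)
        p2 = rng.integers(0, m, size=n_off)
        bad = (pop["MAT_A"][p1] == pop["MAT_A"][p2]) | (
            pop["MAT_B"][p1] == pop["MAT_B"][p2]
        )
        for _ in range(cfg.max_mate_retries):
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            idx = np.nonzero(bad)[0]
            p1[idx] = rng.integers(0, m, size=n_bad)
            p2[idx] = rng.integers(0, m, size=n_bad)
            bad[idx] = (pop["MAT_A"][p1[idx]] == pop["MAT_A"][p2[idx]]) | (
                pop["MAT_B"][p1[idx]] == pop["MAT_B"][p2[idx]]
            )
        failed += int(bad.sum())
        new_pop = {}
        for locus in _WF_LOCI:
            take_first = rng.random(n_off) < 0.5
            new_pop[locus] = np.where(
                take_first, pop[locus][p1], pop[locus][p2]
            )
        pop = new_pop
        if gen == cfg.bottleneck_gen and cfg.bottleneck_size < cfg.pop_size:
            keep = rng.choice(cfg.pop_size, size=cfg.bottleneck_size, replace=False)
            pop = {locus: pop[locus][keep] for locus in _WF_LOCI}
        record(gen)

    trajectories = pd.DataFrame(
        traj_rows, columns=["generation", "locus", "allele", "frequency"]
    )
    richness = pd.DataFrame(
        rich_rows, columns=["generation", "locus", "richness"]
    )
    final = {
        locus: int(len(np.unique(pop[locus]))) for locus in _WF_LOCI
    }
    return WrightFisherResult(
        trajectories=trajectories,
        richness=richness,
        failed_matings=failed,
        final_richness=final,
    )


def wright_fisher_retention(
    cfg: WrightFisherConfig, n_replicates: int = 100
) -> pd.DataFrame:
    """Full-richness retention per locus over independent replicates.

    Runs the simulator ``n_replicates`` times (seeds derived from
    ``cfg.seed``) and reports, per replicate and locus, whether all
    initial alleles survived to the final generation.
    """
    rows = []
    seed_rng = np.random.default_rng(cfg.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_replicates)
    n_init = {"MAT_A": cfg.n_mat_a, "MAT_B": cfg.n_mat_b, "neutral": cfg.n_neutral}
    for rep, seed in enumerate(seeds):
        rep_cfg = WrightFisherConfig(**{**cfg.__dict__, "seed": int(seed)})
        result = simulate_wright_fisher(rep_cfg)
        for locus in _WF_LOCI:
            rows.append(
                (
                    rep,
                    locus,
                    result.final_richness[locus] == n_init[locus],
                    result.final_richness[locus],
                )
            )
    return pd.DataFrame(
        rows, columns=["replicate", "locus", "retained_all", "final_richness"]
    )
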