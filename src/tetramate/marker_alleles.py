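"""Allele calling from MAT-linked marker sequences.

Short marker amplicons (one per locus) distinguish mating-type alleles
by sequence identity. Monokaryons yield one directly sequenced read per
locus; dikaryon amplicons are cloned, so each clone read reports one of
the two alleles and the allele set must be deconvolved from the clone
set. Clustering groups reads into alleles; by default only exact
sequence identity (after trimming) merges reads, with a configurable
identity threshold to absorb sequencing error in simulated data.
"""

from __future__ import annotations

from collections import Counter, defaultdict

from .types import (
    AlleleCatalog,
    Locus,
    MarkerSequence,
    MatingGenotype,
    Ploidy,
)

_LOCUS_PREFIX = {Locus.MAT_A: "A", Locus.MAT_B: "B"}


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Gap-free identity of two trimmed marker sequences.

    Sequences are compared position by position; when lengths differ
    the shorter is end-padded and every padded position counts as a
    mismatch, so identity = matches / max(len1, len2).
    """
    if not seq1 or not seq2:
        raise ValueError("empty sequence")
    matches = sum(1 for a, b in zip(seq1, seq2) if a == b)
    return matches / max(len(seq1), len(seq2))


def cluster_alleles(
    seqs: list[MarkerSequence],
    min_identity: float = 1.0,
) -> tuple[AlleleCatalog, dict[int, str]]:
    """Group same-locus marker reads into alleles by single linkage.

    Two reads join the same cluster when some chain of reads connects
    them with pairwise identity >= ``min_identity``. Each cluster's
    representative is its most frequent exact sequence (ties broken
    lexicographically); labels are assigned by descending cluster size,
    then lexicographic representative, as ``A1``, ``A2``, ... (``B`` for
    MAT B).

    Returns the catalog and a map from input index to allele label.
    The result is invariant under permutation of the input order.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    loci = {s.locus for s in seqs}
    if len(loci) > 1:
        raise ValueError(f"mixed loci in input: {sorted(l.value for l in loci)}")
    locus = loci.pop()
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")

    sequences = [s.sequence.upper() for s in seqs]

    # union-find over unique sequences keeps the pairwise stage small
    unique = sorted(set(sequences))
    parent = list(range(len(unique)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if min_identity < 1.0:
        for i in range(len(unique)):
            for j in range(i + 1, len(unique)):
                if pairwise_identity(unique[i], unique[j]) >= min_identity:
                    union(i, j)

    seq_to_root = {seq: find(i) for i, seq in enumerate(unique)}
    counts = Counter(sequences)
    members: dict[int, list[str]] = defaultdict(list)
    for seq in unique:
        members[seq_to_root[seq]].append(seq)

    clusters = []
    for root, seqs_in in members.items():
        size = sum(counts[s] for s in seqs_in)
        rep = min(seqs_in, key=lambda s: (-counts[s], s))
        clusters.append((size, rep, root))
    # canonical label order: big clusters first, then lexicographic rep
    clusters.sort(key=lambda c: (-c[0], c[1]))

    prefix = _LOCUS_PREFIX[locus]
    root_to_label = {
        root: f"{prefix}{rank}"
        for rank, (_, _, root) in enumerate(clusters, start=1)
    }
    catalog = AlleleCatalog(
        locus=locus,
        alleles=[(root_to_label[root], rep) for _, rep, root in clusters],
    )
    assignment = {
        idx: root_to_label[seq_to_root[seq]]
        for idx, seq in enumerate(sequences)
    }
    return catalog, assignment


def map_catalog_labels(
    catalog: AlleleCatalog,
    reference_labels: dict[str, str],
    auto_suffix: str = "_auto",
) -> tuple[AlleleCatalog, dict[str, str]]:
    """Pin de-novo cluster labels to a reference nomenclature.

    ``reference_labels`` maps representative sequences to the labels
    they should carry. Every reference representative must match
    exactly one cluster; clusters without a reference keep their
    auto-label with ``auto_suffix`` appended. Returns the relabeled
    catalog and the old-label -> new-label map.
    """
    rep_to_old = {rep: label for label, rep in catalog.alleles}
    if len(rep_to_old) != len(catalog.alleles):
        raise ValueError("catalog representatives are not distinct")

    relabel: dict[str, str] = {}
    for ref_rep, ref_label in reference_labels.items():
        matches = [old for rep, old in rep_to_old.items() if rep == ref_rep]
        if not matches:
            raise ValueError(
                f"reference representative for {ref_label} matches no cluster"
            )
        old = matches[0]
        if old in relabel:
            raise ValueError(
                f"ambiguous mapping: cluster {old} matched by multiple "
                "reference representatives"
            )
        relabel[old] = ref_label

    new_alleles = []
    label_map: dict[str, str] = {}
    for old_label, rep in catalog.alleles:
        if old_label in relabel:
            new_label = relabel[old_label]
        elif reference_labels:
            new_label = f"{old_label}{auto_suffix}"
        else:
            new_label = old_label
        label_map[old_label] = new_label
        new_alleles.append((new_label, rep))
    return AlleleCatalog(locus=catalog.locus, alleles=new_alleles), label_map


def call_genotype(
    strain_id: str,
    ploidy: Ploidy,
    assigned: dict[Locus, list[str]],
) -> MatingGenotype:
    """Build a strain genotype from allele labels observed per locus.

    The allele set is the distinct labels observed. A monokaryon with
    two distinct labels at one locus is an error (contamination or
    mislabeled ploidy); a dikaryon with one observed allele is reported
    as incomplete (``*_SINGLE`` flag), never assumed homoallelic.
    """
    a = frozenset(assigned.get(Locus.MAT_A, ()))
    b = frozenset(assigned.get(Locus.MAT_B, ()))
    return MatingGenotype.make(strain_id, ploidy, a, b)
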